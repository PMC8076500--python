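# Methods

## Physical model

Exosomes (50–150 nm extracellular vesicles) are far smaller than any
tissue-scale length of interest, so their population is treated as a
continuum: a concentration field c_k (exosomes·m⁻³) per species k that is
carried by the interstitial fluid and spread by Brownian diffusion,

    ∂c_k/∂t + ∂(u_i c_k)/∂x_i = ∂/∂x_i (Γ_k ∂c_k/∂x_i) + S_ck ,

with interstitial velocity u_i, diffusion coefficient Γ_k and a source term
S_ck for release by tumor cells.  Uptake by immune cells (a sink term) and
any feedback of exosome concentration or interstitial pressure on release
are deliberately excluded: the coupling is strictly one-way from flow to
transport.

The interstitial flow itself is incompressible and laminar.  At the
velocity (≲ 1 μm/s) and length (≲ 1 mm) scales of tissue, the Reynolds
number is ~1e-5–1e-3, so the solver drops the inertial term by default and
solves the Stokes equations; the full laminar Navier–Stokes system is
retained behind `include_inertia=True` (Picard iteration) and agrees with
the Stokes solution to ~1e-6 relative at these parameters, which the test
suite checks.  There is no energy equation and no turbulence model.  The
interstitium is modeled as free fluid around explicitly resolved cell
obstacles; a Darcy/Brinkman porous-medium term is out of scope.

## Discretization

Geometry lives on a uniform cell-centered Cartesian grid (x rightward, y
upward, 0-based `[i, j]` indices with i along x).  Cells whose centers fall
inside a tumor/immune-cell shape are blocked (SOLID); there are no cut
cells.  Faces between fluid and tumor cells are flagged as release faces,
and the prescribed total release rate is distributed over them by face
area, so the imposed rate is honored exactly regardless of rasterization
error.  2-D runs carry an explicit out-of-plane depth (default 1 m,
recorded in every output header) so that concentration integrals are
absolute exosome counts; the transwell uses an axisymmetric (r, z) grid
whose face areas and cell volumes carry the 2πr revolution factor through
the same finite-volume kernels.

**Flow** uses the staggered MAC arrangement (face-normal velocities,
cell-centered pressure), which excludes checkerboard pressure modes.
Momentum on every fluid face and continuity in every fluid cell are
assembled into one sparse saddle-point system and solved directly
(SuperLU) with one step of iterative refinement.  Consequences: the
discrete divergence is at round-off (~1e-12 s⁻¹ or better) in every fluid
cell, and inlet/outlet fluxes balance to ~1e-13 relative — there is no
iterative-convergence tolerance to tune.  Boundary conditions: uniform
velocity on the left inlet, fixed pressure on the right outlet (zero gauge
by default), no-slip on solid surfaces, free-slip (default) or no-slip on
the lateral walls.  Free-slip is the default for tissue runs because the
lateral boundaries there are artificial truncations of a larger tissue,
not physical walls.

**Transport** is a conservative finite-volume scheme.  Advective face
values are reconstructed with a selectable scheme — first-order upwind,
second-order upwind, QUICK (3/8 downstream + 6/8 upstream − 1/8
far-upstream), or MUSCL with a minmod limiter (van Leer selectable) —
falling back to first-order upwind at faces that lack a far-upwind fluid
neighbor.  Diffusive fluxes are central.  Two integrators:

- **explicit** — Heun (RK2) on the full right-hand side, second order in
  time; used for verification so that the O(Δt) error of a first-order
  integrator cannot pollute the measured spatial orders.  The automatic
  step uses the harmonic combination of the advective CFL limit (Courant
  0.5 by default) and the diffusive limit, which keeps the mixed
  amplification factor safely inside the stability region (the bare
  minimum of the two limits is marginal).
- **implicit** (default) — explicit advection plus backward-Euler
  diffusion, unconditional in Γ.  This is required for the transwell,
  where Γ·Δt/Δx² reaches ~1e6 and any explicit step would be ~1e-4 s over
  a 72 h horizon.  The linear solve is done in increment form,
  (V/Δt + L)δ = V·div(Γ∇c*), with the right-hand side evaluated as a flux
  divergence; solving for the full field instead loses ~8 digits to
  cancellation at that stiffness and visibly leaks mass.  With the
  increment form plus one refinement step, closed-domain mass matches the
  released total to ≲1e-9 relative over hundreds of steps.

Wall and solid boundaries carry zero advective and diffusive flux.
Dirichlet values (used for the benchmark's exact-solution boundary and the
tissue outlet c = 0) act on inflowing advection and on the diffusive flux
through a half-cell gradient.  An 'outflow' condition upwinds from the
interior with zero diffusive flux.

## Verification benchmark

A point release of strength M at the origin of the shear flow
u = (U + λy, 0) has the exact solution

    c(x,y,t) = M / (4πDt√(1+(λt)²/12)) ·
               exp{ −[y² + (x − x̄(y,t))²/(1+(λt)²/12)] / 4Dt },

with plume center x̄ = (U + λy/2)·t: particles found at height y today
spent on average half their history at smaller |y|, hence feel half the
local shear.  A sign variant with x̄ = (U − λy/2)·t is also implemented
because it circulates in print; `benchmark.sign_audit` integrates the PDE
on a fine grid from the (variant-indistinguishable) initial field and
measures which variant the numerics converge to.  The '+' variant wins by
three orders of magnitude in L2, and a test pins it as the default.

Defaults: U = 5e-6 m/s, λ = 5e-4 s⁻¹, M = 1, D = 1e-8 m²/s on a
100×100 mm square with the origin at the center.  The solver is
initialized from the exact field at t = 1 min (so the initial condition is
finite; its sampled mass is within 0.5% of M) and integrated for 45 min on
the analytically imposed shear velocity, which is discretely
divergence-free.  Outer boundaries carry the exact solution as a Dirichlet
value; the plume is ~zero there, and this removes boundary ambiguity from
the error norms.  The default 200×200 grid (Δx = 0.5 mm) resolves the
final plume (σ ≈ 7.4 mm) with ≳15 cells.  Error norms are cell-mean L1,
RMS L2 and max L∞ against the exact field, plus horizontal/vertical line
profiles through the analytic peak.  The refinement study (100→200→400,
fixed Courant number) measures observed orders ≈0.9 for first-order upwind
and ≈2.0 for the second/third-order schemes; the MUSCL limiter can clip
slightly below 2 at extrema.

## Transwell scenario

Cells seeded on the floor of a two-chamber well release exosomes at a
measured per-cell rate r (exosomes·h⁻¹ per 1e5 cells): total rate
S = r·(N/1e5)/3600 with N = 3.6e6 cells, giving 5.153 s⁻¹ for the no-force
condition (r = 515.3) and 9.863 s⁻¹ for the oscillatory-force condition
(r = 986.3) — a ratio of 1.914.  The medium is stagnant, so transport is
pure diffusion from a uniform bottom-boundary flux.  The scenario's
diffusion coefficient defaults to 2.0e-3 m²/s.  **Caveat:** that value is
~9 orders of magnitude larger than the Stokes–Einstein estimate for a
50–150 nm vesicle in culture medium (~1e-12 m²/s); it is retained
deliberately as the scenario's published operating point rather than
silently corrected.  Its consequence is a quasi-well-mixed well: vertical
gradients are small (but strictly positive toward the floor at all times,
which a monitor checks) and absolute membrane counts are dominated by
geometry.

The geometry is an axisymmetric body of revolution — well ⌀34.8 mm, insert
⌀24 mm, 2 mm media depth per chamber, insert wall as a solid ring above
the membrane plane — all artifact defaults, since no published dimensions
exist to adopt; absolute membrane counts scale with them and are therefore
qualitative.  The membrane itself (0.4 μm pores, passing 50–150 nm
vesicles freely) is a transparent monitoring plane.  Two counting modes
are provided because "number of exosomes at the membrane" is ambiguous:
`cumulative_flux` (default) integrates the diffusive flux through the
plane over time; `region_content` integrates c over the cell row just
above the plane.  Both modes respond exactly linearly to the release rate
(the PDE is linear with zero initial data), so the OF/NF count ratio
equals the source ratio 1.914 at every time point to round-off — the
package's sharp form of the near-proportionality observed experimentally.
Grid 64×48, 400 steps over 72 h by default (the acceptance checks use a
2 h scaled run with 100 steps; conservation and linearity are
step-count-independent).

## Tumor-microenvironment scenario

A synthetic layout generator stands in for drawn/segmented geometries: a
circular tumor at the center of a 1×1 mm tissue patch (radius 100 μm
early stage; ×1.8 late stage, i.e. 3.24× area) surrounded by
non-overlapping immune cells placed uniformly at random (macrophage
r = 10 μm, T cell r = 6 μm, MDSC r = 8 μm; default counts 10/15/5) with a
5 μm clearance margin.  Layout generation is a pure function of
(stage, counts, seed).  Alternatively a layout can be segmented from a
raster image (Gaussian smoothing, Otsu threshold, connected components;
largest component = tumor) — the round trip render→segment recovers
centers within 2 px and areas within 5% on synthetic images.

Each run solves the steady Stokes flow once (inlet 0.75 μm/s from the
left, zero-gauge outlet on the right, free-slip lateral boundaries,
water-like fluid — the last three being artifact defaults) and then
integrates transport for 45 min on the frozen velocity field with the
tumor surface releasing 2.5 (early) or 7.5 (late) exosomes/s.
Γ defaults to 4.5e-12 m²/s, a Stokes–Einstein estimate for a ~100 nm
vesicle in water at 310 K, making the transport advection-dominated
(Péclet ~ 200 at the domain scale).  Outlet concentration is pinned to
zero (outflow carries exosomes out); default resolution 256².

What the synthetic layouts do and do not emulate: they reproduce the
qualitative structure — a dominant obstacle that both releases exosomes
and obstructs flow, minor obstacles, unidirectional interstitial inflow —
but not any real tissue's cell arrangement, ECM heterogeneity, or
porous-medium drag.  Passing tests therefore support directional claims
(larger tumors raise interstitial pressure and concentrate exosomes; at
fixed geometry concentration scales exactly with release rate) and say
nothing about absolute concentrations in real tissue.  With the shipped
layouts the late/early mean-concentration ratio comes out above the 3×
source ratio (~3.5–4), because the larger tumor also blocks advective
washout and shrinks the dilution volume; only the direction (ratio ≥
source ratio) is a stable prediction, and that is what the tests assert.

## Numerical choices and degenerate inputs

- Grids require at least 4 cells per direction; Γ, Δx, Δy, depth > 0.
- Explicit runs verify Δt against the stability bound and refuse to start
  otherwise; NaN/Inf concentrations abort with step diagnostics.
- A blocked inlet→outlet path, an empty source region, a zero-measure
  membrane, or a layout outside the domain raise typed errors before any
  solve.
- Random placement retries are bounded (default 2000 per cell) and fail
  loudly rather than degrading the layout.
- Ties in the sampled benchmark peak (symmetric values at ±y) resolve to
  the lower index via argmax; tests allow one cell of slack accordingly.
- All outputs (legacy-VTK fields, RFC-4180 monitor CSVs, JSON summaries)
  print float64 with 17 significant digits, making re-reads bitwise and
  identical (config, seed) runs byte-identical.

## Known limitations

- No uptake/sink term, no mechanosensitive release feedback, no tumor
  growth or cell migration: the geometry and rates are frozen inputs.
- Blocked cells make obstacle boundaries first-order accurate; the
  global schemes still measure ~2nd order on smooth obstacle-free
  problems, but near-surface fields around cells are first-order.
- Only left-inlet/right-outlet flow configurations are implemented.
- The axisymmetric transwell assumes the insert is perfectly centered;
  a full 3-D Cartesian cross-check is not included.
- Absolute transwell membrane counts and absolute TME concentrations
  depend on artifact geometry defaults and should be read qualitatively;
  the quantitative claims of this package are the verification errors,
  conservation, linearity ratios, and directional comparisons above.
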