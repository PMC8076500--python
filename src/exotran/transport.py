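"""Unsteady advection-diffusion of exosome concentration on the masked grid.

The exosome population is treated as a continuum scalar c (exosomes per m^3)
obeying

    dc/dt + div(u c) = div(Gamma grad c) + S

with the interstitial velocity u from the flow solver (or imposed), a
constant diffusion coefficient Gamma per species, and source terms S from
tumor-cell release.  The spatial discretization is a conservative finite
volume scheme on the cell-centered grid: advective face values are
reconstructed with a selectable scheme (first/second-order upwind, QUICK, or
MUSCL with a minmod limiter), diffusive fluxes are central.  All fluxes use
the grid's face areas, so the same code runs planar (with an out-of-plane
depth) and axisymmetric (r-z) problems.

Two time integrators are provided: a fully explicit Heun (RK2) step, second
order in time, for verification work; and an operator-split step with
explicit advection and backward-Euler implicit diffusion for stiff problems
(large Gamma or long horizons) where the explicit diffusion limit would be
prohibitive.  Both are conservative to round-off in closed domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, NumericalError
from .flow import VelocityField
from .geometry import DomainMask, Grid

__all__ = [
    "SCHEMES",
    "TransportParams",
    "SourceSpec",
    "BoundarySpec",
    "Boundaries",
    "TransportSolver",
    "TransportHistory",
    "face_value",
    "step_transport",
    "run_transport",
    "total_mass",
    "zero_velocity",
]

SCHEMES = ("upwind1", "upwind2", "quick", "muscl")

BCKind = Literal["wall", "dirichlet", "outflow"]


@dataclass(frozen=True)
class BoundarySpec:
    """One outer-boundary condition.

    kind='wall': zero advective and diffusive flux.
    kind='dirichlet': boundary value (scalar or callable(coords, t) -> array)
    used for inflowing advection and for the diffusive flux.
    kind='outflow': advection upwinds from the interior; zero diffusive flux.
    """

    kind: BCKind = "wall"
    value: float | Callable = 0.0


@dataclass(frozen=True)
class Boundaries:
    left: BoundarySpec = BoundarySpec()
    right: BoundarySpec = BoundarySpec()
    bottom: BoundarySpec = BoundarySpec()
    top: BoundarySpec = BoundarySpec()

    @classmethod
    def walls(cls) -> "Boundaries":
        return cls()

    @classmethod
    def dirichlet(cls, value) -> "Boundaries":
        b = BoundarySpec("dirichlet", value)
        return cls(b, b, b, b)


@dataclass(frozen=True)
class TransportParams:
    """Numerical parameters for one transport run.

    gamma : diffusion coefficient (m^2/s), one value per species.
    scheme : advective face reconstruction in :data:`SCHEMES`.
    dt : time step (s); None selects it automatically from the CFL number,
        the explicit diffusion limit (explicit integrator only) and a
        target of at least 200 steps per run.
    t_end : integration horizon (s).
    integrator : 'implicit' (backward-Euler diffusion, default) or
        'explicit' (Heun RK2 on the full right-hand side).
    cfl : advective Courant number used when dt is automatic.
    limiter : MUSCL slope limiter, 'minmod' (default) or 'vanleer'.
    """

    gamma: float = 1e-12
    scheme: str = "quick"
    dt: float | None = None
    t_end: float = 0.0
    integrator: Literal["implicit", "explicit"] = "implicit"
    cfl: float = 0.5
    limiter: Literal["minmod", "vanleer"] = "minmod"

    def __post_init__(self):
        if self.gamma <= 0:
            raise ConfigurationError("diffusion coefficient must be > 0")
        if self.scheme not in SCHEMES:
            raise ConfigurationError(
                f"unknown scheme {self.scheme!r}; choose from {SCHEMES}"
            )
        if self.dt is not None and self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not 0 < self.cfl <= 1:
            raise ConfigurationError("cfl must be in (0, 1]")


@dataclass
class SourceSpec:
    """Exosome release: a total rate distributed uniformly over a region.

    region : 'tumor_faces' distributes over the mask's SOURCE faces by face
        area (release through the tumor surface); 'bottom' over the domain's
        bottom boundary faces (cells seeded on the vessel floor); or a
        boolean (nx, ny) cell array for a volumetric source.
    total_rate : exosomes per second; the distributed cell rates sum to
        this exactly.
    """

    total_rate: float
    region: str | np.ndarray = "tumor_faces"

    def __post_init__(self):
        if self.total_rate < 0:
            raise ConfigurationError("release rate must be >= 0")

    def cell_rates(self, grid: Grid, mask: DomainMask) -> np.ndarray:
        """Per-cell injection rates Q (exosomes/s), Q.sum() == total_rate."""
        nx, ny = grid.nx, grid.ny
        Q = np.zeros((nx, ny))
        if isinstance(self.region, np.ndarray):
            region = self.region & mask.fluid
            if not region.any():
                raise ConfigurationError("volumetric source region has no fluid cells")
            w = grid.cell_volume * region
        elif self.region == "tumor_faces":
            if mask.n_source_faces == 0:
                raise ConfigurationError("mask has no SOURCE faces")
            w = np.zeros((nx, ny))
            ax, ay = grid.face_area_x, grid.face_area_y
            sx, sy = mask.source_x, mask.source_y
            # each tumor-boundary face injects into its fluid neighbor
            for i, j in zip(*np.nonzero(sx)):
                if i < nx and mask.fluid[i, j]:
                    w[i, j] += ax[i, j]
                elif i > 0 and mask.fluid[i - 1, j]:
                    w[i - 1, j] += ax[i, j]
            for i, j in zip(*np.nonzero(sy)):
                if j < ny and mask.fluid[i, j]:
                    w[i, j] += ay[i, j]
                elif j > 0 and mask.fluid[i, j - 1]:
                    w[i, j - 1] += ay[i, j]
        elif self.region == "bottom":
            cols = mask.fluid[:, 0]
            if not cols.any():
                raise ConfigurationError("no fluid cells on the bottom boundary")
            w = np.zeros((nx, ny))
            w[:, 0] = grid.face_area_y[:, 0] * cols
        else:
            raise ConfigurationError(f"unknown source region {self.region!r}")
        total_w = w.sum()
        if total_w <= 0:
            raise ConfigurationError("source region has zero measure")
        Q[:] = self.total_rate * w / total_w
        return Q


def zero_velocity(grid: Grid) -> VelocityField:
    """Stagnant medium: all face velocities zero (diffusion-only transport)."""
    return VelocityField(
        np.zeros((grid.nx + 1, grid.ny)), np.zeros((grid.nx, grid.ny + 1))
    )


def total_mass(c: np.ndarray, grid: Grid, mask: DomainMask) -> float:
    """Absolute exosome count: sum of c * cell volume over FLUID cells."""
    return float((c * grid.cell_volume)[mask.fluid].sum())


# ---------------------------------------------------------------------------
# Face reconstruction
# ---------------------------------------------------------------------------

def _minmod(a, b):
    return np.where(a * b > 0, np.where(np.abs(a) < np.abs(b), a, b), 0.0)


def _vanleer(a, b):
    denom = np.abs(a) + np.abs(b)
    return np.where(a * b > 0, 2 * a * b / np.where(denom == 0, 1.0, denom), 0.0)


def face_value(
    stencil: Sequence[float], velocity_sign: float, scheme: str, limiter: str = "minmod"
) -> float:
    """Reconstruct the advected face value from a coordinate-ordered stencil.

    ``stencil`` holds 2-4 consecutive cell values in increasing coordinate
    order.  For positive velocity the face is between the last two values;
    for negative velocity between the first two, mirroring the upwind bias.
    Falls back to first-order upwind when the stencil is too short for the
    requested scheme.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    vals = [float(v) for v in stencil]
    if any(not np.isfinite(v) for v in vals):
        raise ConfigurationError("stencil values must be finite")
    if len(vals) < 2:
        raise ConfigurationError("stencil needs at least 2 values")
    if velocity_sign >= 0:
        c_uu, c_u, c_d = (vals[-3] if len(vals) >= 3 else None), vals[-2], vals[-1]
    else:
        vals = vals[::-1]
        c_uu, c_u, c_d = (vals[-3] if len(vals) >= 3 else None), vals[-2], vals[-1]
    if scheme == "upwind1" or c_uu is None:
        return c_u
    if scheme == "upwind2":
        return 1.5 * c_u - 0.5 * c_uu
    if scheme == "quick":
        return (6.0 * c_u + 3.0 * c_d - c_uu) / 8.0
    # muscl
    lim = _minmod if limiter == "minmod" else _vanleer
    return c_u + 0.5 * float(lim(np.asarray(c_u - c_uu), np.asarray(c_d - c_u)))


def _reconstruct(c, q_pos, scheme, limiter, axis):
    """Vectorized interior-face reconstruction along ``axis`` (0=x, 1=y).

    ``c`` is (nx, ny); returns face values for interior faces (nx-1 or ny-1
    along the axis).  ``q_pos`` is the boolean positive-velocity mask on
    those faces.  Faces lacking a far-upwind neighbor fall back to
    first-order upwind.
    """
    if axis == 1:
        return _reconstruct(c.T, q_pos.T, scheme, limiter, 0).T
    n = c.shape[0]
    cW = c[:-1, :]  # west cell of face f=1..n-1
    cE = c[1:, :]
    c_u = np.where(q_pos, cW, cE)
    if scheme == "upwind1":
        return c_u
    c_d = np.where(q_pos, cE, cW)
    # far-upwind: index f-2 for positive, f+1 for negative
    c_uu = np.empty_like(c_u)
    valid = np.empty_like(q_pos)
    # positive velocity
    c_uu_pos = np.full_like(c_u, np.nan)
    c_uu_pos[1:, :] = c[:-2, :]
    # negative velocity
    c_uu_neg = np.full_like(c_u, np.nan)
    c_uu_neg[:-1, :] = c[2:, :]
    c_uu = np.where(q_pos, c_uu_pos, c_uu_neg)
    valid = np.isfinite(c_uu)
    c_uu = np.where(valid, c_uu, c_u)
    if scheme == "upwind2":
        high = 1.5 * c_u - 0.5 * c_uu
    elif scheme == "quick":
        high = (6.0 * c_u + 3.0 * c_d - c_uu) / 8.0
    else:  # muscl
        lim = _minmod if limiter == "minmod" else _vanleer
        high = c_u + 0.5 * lim(c_u - c_uu, c_d - c_u)
    return np.where(valid, high, c_u)


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass
class TransportHistory:
    """Monitor time series plus checkpointed fields from one run."""

    times: np.ndarray
    monitors: dict[str, np.ndarray]
    checkpoints: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def monitor(self, name: str) -> np.ndarray:
        return self.monitors[name]


class TransportSolver:
    """Finite-volume advection-diffusion integrator bound to one geometry.

    Prebuilds face masks, scheme fallbacks and (for the implicit integrator)
    the factorized backward-Euler diffusion operator, then advances the
    concentration with :meth:`step` or :meth:`run`.
    """

    def __init__(
        self,
        grid: Grid,
        mask: DomainMask,
        params: TransportParams,
        velocity: VelocityField | None = None,
        sources: Sequence[SourceSpec] = (),
        boundaries: Boundaries | None = None,
    ):
        self.grid = grid
        self.mask = mask
        self.params = params
        self.vel = velocity if velocity is not None else zero_velocity(grid)
        self.bcs = boundaries if boundaries is not None else Boundaries.walls()
        self.Q = sum(
            (s.cell_rates(grid, mask) for s in sources),
            start=np.zeros((grid.nx, grid.ny)),
        )
        fluid = mask.fluid
        # faces between two fluid cells carry flux
        self.open_x = np.zeros((grid.nx + 1, grid.ny), bool)
        self.open_x[1:-1, :] = fluid[:-1, :] & fluid[1:, :]
        self.open_y = np.zeros((grid.nx, grid.ny + 1), bool)
        self.open_y[:, 1:-1] = fluid[:, :-1] & fluid[:, 1:]
        # boundary faces open to the exterior (non-wall BCs on fluid cells)
        self.qx = self.vel.u * grid.face_area_x  # volumetric face fluxes
        self.qy = self.vel.v * grid.face_area_y
        self.dt = params.dt if params.dt is not None else self._auto_dt()
        if params.integrator == "explicit":
            lim = self._explicit_dt_limit()
            if self.dt > lim * (1 + 1e-12):
                raise ConfigurationError(
                    f"dt={self.dt:g} s exceeds the explicit stability limit "
                    f"{lim:g} s; reduce dt or use the implicit integrator"
                )
        else:
            self._lu = self._build_diffusion_lu(self.dt)
        self._mass_released = 0.0

    # -- time step selection ----------------------------------------------
    def _advective_dt_limit(self) -> float:
        g = self.grid
        umax = max(np.abs(self.vel.u).max() / g.dx, np.abs(self.vel.v).max() / g.dy)
        return self.params.cfl / umax if umax > 0 else np.inf

    def _explicit_dt_limit(self) -> float:
        g = self.grid
        adv = self._advective_dt_limit()
        dif = 1.0 / (2 * self.params.gamma * (1 / g.dx**2 + 1 / g.dy**2))
        return min(adv, dif)

    def _auto_dt(self) -> float:
        t_end = self.params.t_end
        dt = t_end / 200 if t_end > 0 else 1.0
        dt = min(dt, self._advective_dt_limit())
        if self.params.integrator == "explicit":
            # harmonic combination keeps the mixed advection-diffusion
            # amplification safely inside the stability region
            g = self.grid
            dif = 1.0 / (2 * self.params.gamma * (1 / g.dx**2 + 1 / g.dy**2))
            adv = self._advective_dt_limit()
            dt = min(dt, 1.0 / (1.0 / adv + 1.0 / dif) if np.isfinite(adv) else dif)
        return dt

    # -- boundary helpers ---------------------------------------------------
    def _bc_value(self, spec: BoundarySpec, coords, t):
        if callable(spec.value):
            return np.asarray(spec.value(coords, t), float)
        return np.full(len(coords), float(spec.value))

    def _boundary_coords(self, side: str):
        g = self.grid
        if side in ("left", "right"):
            x = g.xf[0] if side == "left" else g.xf[-1]
            return np.column_stack([np.full(g.ny, x), g.yc])
        y = g.yf[0] if side == "bottom" else g.yf[-1]
        return np.column_stack([g.xc, np.full(g.nx, y)])

    # -- right-hand side pieces --------------------------------------------
    def advective_divergence(self, c: np.ndarray, t: float) -> np.ndarray:
        """-div(u c) per cell (concentration per second), flux form."""
        g, p = self.grid, self.params
        Fx = np.zeros((g.nx + 1, g.ny))
        Fy = np.zeros((g.nx, g.ny + 1))
        # interior faces
        qxi = self.qx[1:-1, :]
        cfx = _reconstruct(c, qxi >= 0, p.scheme, p.limiter, axis=0)
        Fx[1:-1, :] = np.where(self.open_x[1:-1, :], qxi * cfx, 0.0)
        qyi = self.qy[:, 1:-1]
        cfy = _reconstruct(c, qyi >= 0, p.scheme, p.limiter, axis=1)
        Fy[:, 1:-1] = np.where(self.open_y[:, 1:-1], qyi * cfy, 0.0)
        # boundary faces
        for side, spec in (
            ("left", self.bcs.left),
            ("right", self.bcs.right),
            ("bottom", self.bcs.bottom),
            ("top", self.bcs.top),
        ):
            if spec.kind == "wall":
                continue
            if side == "left":
                q, interior, fl = self.qx[0, :], c[0, :], self.mask.fluid[0, :]
            elif side == "right":
                q, interior, fl = self.qx[-1, :], c[-1, :], self.mask.fluid[-1, :]
            elif side == "bottom":
                q, interior, fl = self.qy[:, 0], c[:, 0], self.mask.fluid[:, 0]
            else:
                q, interior, fl = self.qy[:, -1], c[:, -1], self.mask.fluid[:, -1]
            outward = q > 0 if side in ("right", "top") else q < 0
            if spec.kind == "dirichlet":
                bval = self._bc_value(spec, self._boundary_coords(side), t)
            else:  # outflow: upwind from interior either way
                bval = interior
            cface = np.where(outward, interior, bval) * fl
            F = q * cface
            if side == "left":
                Fx[0, :] = F
            elif side == "right":
                Fx[-1, :] = F
            elif side == "bottom":
                Fy[:, 0] = F
            else:
                Fy[:, -1] = F
        net = Fx[1:, :] - Fx[:-1, :] + Fy[:, 1:] - Fy[:, :-1]
        return -net / g.cell_volume

    def diffusive_divergence(self, c: np.ndarray, t: float) -> np.ndarray:
        """div(Gamma grad c) per cell (explicit evaluation)."""
        g = self.grid
        gam = self.params.gamma
        Fx = np.zeros((g.nx + 1, g.ny))
        Fy = np.zeros((g.nx, g.ny + 1))
        Fx[1:-1, :] = np.where(
            self.open_x[1:-1, :],
            -gam * g.face_area_x[1:-1, :] * (c[1:, :] - c[:-1, :]) / g.dx,
            0.0,
        )
        Fy[:, 1:-1] = np.where(
            self.open_y[:, 1:-1],
            -gam * g.face_area_y[:, 1:-1] * (c[:, 1:] - c[:, :-1]) / g.dy,
            0.0,
        )
        for side, spec in (
            ("left", self.bcs.left),
            ("right", self.bcs.right),
            ("bottom", self.bcs.bottom),
            ("top", self.bcs.top),
        ):
            if spec.kind != "dirichlet":
                continue
            bval = self._bc_value(spec, self._boundary_coords(side), t)
            if side == "left":
                fl = self.mask.fluid[0, :]
                Fx[0, :] = -gam * g.face_area_x[0, :] * (c[0, :] - bval) / (0.5 * g.dx) * fl
            elif side == "right":
                fl = self.mask.fluid[-1, :]
                Fx[-1, :] = -gam * g.face_area_x[-1, :] * (bval - c[-1, :]) / (0.5 * g.dx) * fl
            elif side == "bottom":
                fl = self.mask.fluid[:, 0]
                Fy[:, 0] = -gam * g.face_area_y[:, 0] * (c[:, 0] - bval) / (0.5 * g.dy) * fl
            else:
                fl = self.mask.fluid[:, -1]
                Fy[:, -1] = -gam * g.face_area_y[:, -1] * (bval - c[:, -1]) / (0.5 * g.dy) * fl
        net = Fx[1:, :] - Fx[:-1, :] + Fy[:, 1:] - Fy[:, :-1]
        return -net / g.cell_volume

    def source_rate(self) -> np.ndarray:
        """dc/dt from sources (concentration per second per cell)."""
        return self.Q / self.grid.cell_volume

    # -- implicit diffusion operator ---------------------------------------
    def _build_diffusion_lu(self, dt: float):
        g, mask = self.grid, self.mask
        nx, ny = g.nx, g.ny
        gam = self.params.gamma
        n = nx * ny
        idx = np.arange(n).reshape(nx, ny)
        rows, cols, vals = [], [], []
        V = g.cell_volume.ravel()
        diag = V / dt
        # interior fluid-fluid faces: conductance G = gam*A/d
        Gx = gam * g.face_area_x[1:-1, :] / g.dx * self.open_x[1:-1, :]
        Gy = gam * g.face_area_y[:, 1:-1] / g.dy * self.open_y[:, 1:-1]
        iw, jw = np.nonzero(Gx)
        a = idx[iw, jw]
        b = idx[iw + 1, jw]
        gv = Gx[iw, jw]
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-gv, -gv, gv, gv]
        iw, jw = np.nonzero(Gy)
        a = idx[iw, jw]
        b = idx[iw, jw + 1]
        gv = Gy[iw, jw]
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-gv, -gv, gv, gv]
        # Dirichlet boundary conductances (constant values only; added to diag)
        self._dir_rhs = np.zeros((nx, ny))
        bd_diag = np.zeros((nx, ny))
        for side, spec in (
            ("left", self.bcs.left),
            ("right", self.bcs.right),
            ("bottom", self.bcs.bottom),
            ("top", self.bcs.top),
        ):
            if spec.kind != "dirichlet":
                continue
            if callable(spec.value):
                raise ConfigurationError(
                    "implicit integrator supports constant Dirichlet values only"
                )
            val = float(spec.value)
            if side == "left":
                G = gam * g.face_area_x[0, :] / (0.5 * g.dx) * mask.fluid[0, :]
                bd_diag[0, :] += G
                self._dir_rhs[0, :] += G * val
            elif side == "right":
                G = gam * g.face_area_x[-1, :] / (0.5 * g.dx) * mask.fluid[-1, :]
                bd_diag[-1, :] += G
                self._dir_rhs[-1, :] += G * val
            elif side == "bottom":
                G = gam * g.face_area_y[:, 0] / (0.5 * g.dy) * mask.fluid[:, 0]
                bd_diag[:, 0] += G
                self._dir_rhs[:, 0] += G * val
            else:
                G = gam * g.face_area_y[:, -1] / (0.5 * g.dy) * mask.fluid[:, -1]
                bd_diag[:, -1] += G
                self._dir_rhs[:, -1] += G * val
        rows.append(idx.ravel())
        cols.append(idx.ravel())
        vals.append(diag + bd_diag.ravel())
        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self._A_diff = A
        return spla.splu(A)

    # -- stepping ------------------------------------------------------------
    def step(self, c: np.ndarray, t: float, dt: float | None = None) -> np.ndarray:
        """Advance one time step from time ``t``; returns the new field."""
        dt = self.dt if dt is None else dt
        g = self.grid
        src = self.source_rate()
        if self.params.integrator == "explicit":
            def rhs(cc, tt):
                return (
                    self.advective_divergence(cc, tt)
                    + self.diffusive_divergence(cc, tt)
                    + src
                )

            k1 = rhs(c, t)
            k2 = rhs(c + dt * k1, t + dt)
            c_new = c + 0.5 * dt * (k1 + k2)
        else:
            if dt != self.dt:
                self._lu = self._build_diffusion_lu(dt)
                self.dt = dt
            c_star = c + dt * (self.advective_divergence(c, t) + src)
            # increment form: (V/dt + L) delta = V * div(Gamma grad c*);
            # the flux-form right-hand side avoids the cancellation that a
            # direct solve for c suffers when Gamma*dt/dx^2 is large, keeping
            # the conservation defect at round-off
            b = (g.cell_volume * self.diffusive_divergence(c_star, t + dt)).ravel()
            delta = self._lu.solve(b)
            delta += self._lu.solve(b - self._A_diff @ delta)
            c_new = c_star + delta.reshape(g.nx, g.ny)
        c_new = np.where(self.mask.fluid, c_new, 0.0)
        if not np.all(np.isfinite(c_new[self.mask.fluid])):
            raise NumericalError(
                f"non-finite concentration after step at t={t:g} s (dt={dt:g})"
            )
        self._mass_released += self.Q.sum() * dt
        return c_new

    def run(
        self,
        c0: np.ndarray,
        t0: float = 0.0,
        monitors: dict[str, Callable] | None = None,
        n_checkpoints: int = 0,
    ) -> TransportHistory:
        """Integrate from ``t0`` to ``t0 + t_end``; record monitors each step.

        ``monitors`` maps names to callables (t, c) -> float; a 'total_mass'
        monitor is always included.  ``n_checkpoints`` evenly spaced field
        snapshots (plus the final field) are stored in the history.
        """
        t_end = self.params.t_end
        if t_end <= 0:
            raise ConfigurationError("params.t_end must be positive for run()")
        mons = {"total_mass": lambda t, c: total_mass(c, self.grid, self.mask)}
        if monitors:
            mons.update(monitors)
        n_steps = int(np.ceil(t_end / self.dt - 1e-12))
        dt = t_end / n_steps
        if self.params.integrator == "implicit" and dt != self.dt:
            self._lu = self._build_diffusion_lu(dt)
        self.dt = dt
        ck_every = max(1, n_steps // n_checkpoints) if n_checkpoints else None

        c = np.where(self.mask.fluid, np.asarray(c0, float), 0.0)
        times = [t0]
        series = {k: [f(t0, c)] for k, f in mons.items()}
        checkpoints = [(t0, c.copy())] if n_checkpoints else []
        t = t0
        for istep in range(1, n_steps + 1):
            c = self.step(c, t, dt)
            t = t0 + istep * dt
            times.append(t)
            for k, f in mons.items():
                series[k].append(f(t, c))
            if ck_every and (istep % ck_every == 0 or istep == n_steps):
                checkpoints.append((t, c.copy()))
        return TransportHistory(
            times=np.asarray(times),
            monitors={k: np.asarray(v) for k, v in series.items()},
            checkpoints=checkpoints,
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def step_transport(
    c: np.ndarray,
    velocity: VelocityField | None,
    params: TransportParams,
    sources: Sequence[SourceSpec],
    dt: float,
    grid: Grid,
    mask: DomainMask,
    boundaries: Boundaries | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """One conservative finite-volume update (see :class:`TransportSolver`)."""
    solver = TransportSolver(
        grid, mask, params, velocity=velocity, sources=sources, boundaries=boundaries
    )
    return solver.step(np.asarray(c, float), t, dt)


def run_transport(
    c0: np.ndarray,
    velocity: VelocityField | None,
    params: TransportParams,
    sources: Sequence[SourceSpec],
    grid: Grid,
    mask: DomainMask,
    boundaries: Boundaries | None = None,
    monitors: dict[str, Callable] | None = None,
    n_checkpoints: int = 0,
    t0: float = 0.0,
) -> TransportHistory:
    """Integrate the transport equation over ``params.t_end`` seconds."""
    solver = TransportSolver(
        grid, mask, params, velocity=velocity, sources=sources, boundaries=boundaries
    )
    return solver.run(c0, t0=t0, monitors=monitors, n_checkpoints=n_checkpoints)
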