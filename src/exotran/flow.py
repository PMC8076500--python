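"""Steady incompressible interstitial flow on the masked Cartesian grid.

Interstitial fluid in tissue moves at micrometers per second over sub-mm
distances, so the Reynolds number is ~1e-5..1e-3 and the flow is laminar and
effectively inertia-free.  The default solver therefore drops the convective
term and solves the Stokes equations

    mu * lap(u) = grad p,    div u = 0

on a staggered (MAC) arrangement: face-normal velocities, cell-centered
pressure.  The discrete saddle-point system (momentum on every fluid face,
continuity in every fluid cell) is assembled sparse and solved directly, so
the converged divergence is at round-off level in every fluid cell.  The
full laminar Navier-Stokes equations are available behind
``include_inertia=True`` via Picard iteration on the convective term.

Boundary conditions: uniform-velocity inlet on the left side, fixed-pressure
outlet on the right, no-slip on solid (cell) surfaces, and either free-slip
(default) or no-slip lateral walls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .errors import ConfigurationError, GeometryError, SolverError
from .geometry import DomainMask, Grid

__all__ = [
    "FluidProps",
    "FlowBCs",
    "VelocityField",
    "PressureField",
    "solve_flow",
    "reynolds_number",
    "compute_streamlines",
    "divergence",
]


@dataclass(frozen=True)
class FluidProps:
    """Incompressible fluid: density (kg/m^3) and dynamic viscosity (Pa s).

    Defaults are water-like, a conventional stand-in for interstitial fluid.
    """

    density: float = 1000.0
    viscosity: float = 1.0e-3

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ConfigurationError("density and viscosity must be positive")


@dataclass(frozen=True)
class FlowBCs:
    """Inlet/outlet/wall boundary conditions.

    inlet_side / outlet_side: currently 'left' and 'right' respectively
    (flow enters from the left of the domain).  ``lateral``: treatment of
    the top/bottom walls.
    """

    inlet_velocity: float
    outlet_pressure: float = 0.0
    inlet_side: Literal["left"] = "left"
    outlet_side: Literal["right"] = "right"
    lateral: Literal["slip", "noslip"] = "slip"

    def __post_init__(self):
        if self.inlet_velocity < 0:
            raise ConfigurationError("inlet velocity magnitude must be >= 0")
        if self.inlet_side != "left" or self.outlet_side != "right":
            raise ConfigurationError(
                "only left inlet / right outlet are supported"
            )


@dataclass
class VelocityField:
    """Face-normal velocities on the MAC grid: u (nx+1, ny), v (nx, ny+1)."""

    u: np.ndarray
    v: np.ndarray

    @property
    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max())

    def at_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centered velocity components by face averaging."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc


@dataclass
class PressureField:
    """Cell-centered pressure (Pa), defined up to the outlet reference."""

    p: np.ndarray


def divergence(grid: Grid, vel: VelocityField) -> np.ndarray:
    """Discrete divergence (1/s) per cell from face fluxes."""
    qx = vel.u * grid.face_area_x
    qy = vel.v * grid.face_area_y
    return (qx[1:, :] - qx[:-1, :] + qy[:, 1:] - qy[:, :-1]) / grid.cell_volume


def reynolds_number(props: FluidProps, U: float, L: float) -> float:
    """Re = rho U L / mu for velocity scale U (m/s) and length scale L (m)."""
    if U < 0 or L <= 0:
        raise ConfigurationError("U must be >= 0 and L > 0")
    return props.density * U * L / props.viscosity


def _check_connectivity(mask: DomainMask) -> None:
    labels, _ = ndimage.label(mask.fluid)
    inlet_labels = set(np.unique(labels[0, :])) - {0}
    outlet_labels = set(np.unique(labels[-1, :])) - {0}
    if not (inlet_labels & outlet_labels):
        raise GeometryError("no connected FLUID path from inlet to outlet")


def _assemble_stokes(grid: Grid, mask: DomainMask, props: FluidProps, bcs: FlowBCs):
    """Assemble the coupled (u, v, p) saddle-point system.

    Returns the matrix, base right-hand side, u/v unknown counts and boolean
    arrays marking interior-momentum u/v rows (where a convective forcing
    may later be added to the right-hand side).
    """
    nx, ny = grid.nx, grid.ny
    dx, dy = grid.dx, grid.dy
    mu = props.viscosity
    fluid = mask.fluid
    nu = (nx + 1) * ny
    nv = nx * (ny + 1)
    n = nu + nv + nx * ny

    def uid(i, j):
        return i * ny + j

    def vid(i, j):
        return nu + i * (ny + 1) + j

    def pid(i, j):
        return nu + nv + i * ny + j

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(n)
    u_interior = np.zeros((nx + 1, ny), bool)
    v_interior = np.zeros((nx, ny + 1), bool)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    slip = bcs.lateral == "slip"

    # --- u momentum -------------------------------------------------------
    for i in range(nx + 1):
        for j in range(ny):
            r = uid(i, j)
            if i == 0:
                add(r, r, 1.0)
                rhs[r] = bcs.inlet_velocity if fluid[0, j] else 0.0
                continue
            left_fluid = fluid[i - 1, j]
            right_fluid = fluid[i, j] if i < nx else True  # outlet open
            if not (left_fluid and right_fluid):
                add(r, r, 1.0)  # no-slip on solid surfaces
                continue
            diag = 0.0
            # x-direction viscous neighbors
            if i - 1 >= 0:
                add(r, uid(i - 1, j), mu / dx**2)
                diag -= mu / dx**2
            if i + 1 <= nx:
                add(r, uid(i + 1, j), mu / dx**2)
                diag -= mu / dx**2
            # else: outlet ghost du/dx = 0 -> no contribution
            # y-direction viscous neighbors (walls via ghost values)
            for dj in (-1, 1):
                jj = j + dj
                if 0 <= jj < ny:
                    add(r, uid(i, jj), mu / dy**2)
                    diag -= mu / dy**2
                elif not slip:
                    diag -= 2.0 * mu / dy**2  # no-slip ghost = -u
                # slip ghost = u: zero net contribution
            u_interior[i, j] = True
            add(r, r, diag)
            # pressure gradient
            if i < nx:
                add(r, pid(i, j), -1.0 / dx)
                add(r, pid(i - 1, j), 1.0 / dx)
            else:  # outlet face: outside pressure fixed at the reference
                add(r, pid(i - 1, j), 1.0 / dx)
                rhs[r] -= bcs.outlet_pressure / dx
    # --- v momentum -------------------------------------------------------
    for i in range(nx):
        for j in range(ny + 1):
            r = vid(i, j)
            if j == 0 or j == ny:
                add(r, r, 1.0)  # impermeable top/bottom walls
                continue
            if not (fluid[i, j - 1] and fluid[i, j]):
                add(r, r, 1.0)
                continue
            diag = 0.0
            for di in (-1, 1):
                ii = i + di
                if 0 <= ii < nx:
                    add(r, vid(ii, j), mu / dx**2)
                    diag -= mu / dx**2
                elif ii < 0:
                    diag -= 2.0 * mu / dx**2  # inlet plane: v = 0 ghost
                # outlet ghost dv/dx = 0: no contribution
            for dj in (-1, 1):
                add(r, vid(i, j + dj), mu / dy**2)
                diag -= mu / dy**2
            v_interior[i, j] = True
            add(r, r, diag)
            add(r, pid(i, j), -1.0 / dy)
            add(r, pid(i, j - 1), 1.0 / dy)
    # --- continuity -------------------------------------------------------
    for i in range(nx):
        for j in range(ny):
            r = pid(i, j)
            if not fluid[i, j]:
                add(r, r, 1.0)  # pressure placeholder in solids
                continue
            add(r, uid(i + 1, j), 1.0 / dx)
            add(r, uid(i, j), -1.0 / dx)
            add(r, vid(i, j + 1), 1.0 / dy)
            add(r, vid(i, j), -1.0 / dy)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return A, rhs, nu, nv, u_interior, v_interior


def _convective_terms(grid: Grid, vel: VelocityField):
    """Upwind-free central estimate of (u . grad)u at u- and v-faces (m/s^2)."""
    u, v = vel.u, vel.v
    dx, dy = grid.dx, grid.dy
    conv_u = np.zeros_like(u)
    # interior u faces
    dudx = np.zeros_like(u)
    dudx[1:-1, :] = (u[2:, :] - u[:-2, :]) / (2 * dx)
    dudy = np.zeros_like(u)
    dudy[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2 * dy)
    # v interpolated to u faces (interior)
    v_at_u = np.zeros_like(u)
    v_at_u[1:-1, :] = 0.25 * (
        v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:]
    )
    conv_u = u * dudx + v_at_u * dudy

    conv_v = np.zeros_like(v)
    dvdx = np.zeros_like(v)
    dvdx[1:-1, :] = (v[2:, :] - v[:-2, :]) / (2 * dx)
    dvdy = np.zeros_like(v)
    dvdy[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2 * dy)
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:-1] = 0.25 * (
        u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:]
    )
    conv_v = u_at_v * dvdx + v * dvdy
    return conv_u, conv_v


def solve_flow(
    grid: Grid,
    mask: DomainMask,
    props: FluidProps,
    bcs: FlowBCs,
    tol: float = 1e-8,
    include_inertia: bool = False,
    max_picard: int = 30,
) -> tuple[VelocityField, PressureField]:
    """Solve steady incompressible flow; returns (velocity, pressure).

    Stokes flow (default) is a single sparse direct solve.  With
    ``include_inertia`` the convective term is added by Picard iteration
    until the relative velocity update falls below ``tol``; at interstitial
    Reynolds numbers this converges in a couple of iterations.

    Raises
    ------
    GeometryError
        If no fluid path connects inlet to outlet.
    SolverError
        If the Picard iteration does not converge within ``max_picard``.
    """
    if grid.spec.coordinates != "cartesian":
        raise ConfigurationError("flow solver supports Cartesian grids only")
    _check_connectivity(mask)
    nx, ny = grid.nx, grid.ny

    A, rhs0, nu, nv, u_int, v_int = _assemble_stokes(grid, mask, props, bcs)
    lu = spla.splu(A)

    def solve(rhs):
        s = lu.solve(rhs)
        s += lu.solve(rhs - A @ s)  # one step of iterative refinement
        return s

    sol = solve(rhs0)
    u = sol[:nu].reshape(nx + 1, ny)
    v = sol[nu:nu + nv].reshape(nx, ny + 1)
    p = sol[nu + nv:].reshape(nx, ny)
    vel = VelocityField(u, v)

    if include_inertia and bcs.inlet_velocity > 0:
        history = []
        for _ in range(max_picard):
            conv_u, conv_v = _convective_terms(grid, vel)
            rhs = rhs0.copy()
            rhs[:nu][u_int.ravel()] -= props.density * conv_u[u_int]
            rhs[nu:nu + nv][v_int.ravel()] -= props.density * conv_v[v_int]
            sol = solve(rhs)
            u_new = sol[:nu].reshape(nx + 1, ny)
            v_new = sol[nu:nu + nv].reshape(nx, ny + 1)
            scale = max(np.abs(u_new).max(), np.abs(v_new).max(), 1e-300)
            change = max(
                np.abs(u_new - vel.u).max(), np.abs(v_new - vel.v).max()
            ) / scale
            history.append(change)
            vel = VelocityField(u_new, v_new)
            p = sol[nu + nv:].reshape(nx, ny)
            if change < tol:
                break
        else:
            raise SolverError(
                f"Picard iteration for inertia did not reach {tol:g} "
                f"in {max_picard} iterations",
                residual_history=history,
            )

    p = np.where(mask.fluid, p, 0.0)
    return vel, PressureField(p)


def mass_balance(grid: Grid, mask: DomainMask, vel: VelocityField) -> tuple[float, float]:
    """(inlet volumetric flux, outlet volumetric flux) in m^3/s."""
    qin = float((vel.u[0, :] * grid.face_area_x[0, :] * mask.fluid[0, :]).sum())
    qout = float((vel.u[-1, :] * grid.face_area_x[-1, :] * mask.fluid[-1, :]).sum())
    return qin, qout


def compute_streamlines(
    grid: Grid,
    mask: DomainMask,
    vel: VelocityField,
    seed_points: np.ndarray,
    step: float | None = None,
    max_len: float | None = None,
) -> list[np.ndarray]:
    """Trace streamlines through the velocity field by RK4 integration.

    ``seed_points`` is (n, 2) in meters.  ``step`` is the arc-length step
    (default: half a cell); ``max_len`` caps the total arc length (default:
    4x the domain diagonal).  Integration stops at domain boundaries, solid
    cells, or stagnation.  Seeds inside solids are skipped with a warning.
    Returns a list of (m, 2) polylines.
    """
    from scipy.interpolate import RegularGridInterpolator

    xmin, xmax, ymin, ymax = grid.extent
    if step is None:
        step = 0.5 * min(grid.dx, grid.dy)
    if max_len is None:
        max_len = 4.0 * np.hypot(xmax - xmin, ymax - ymin)
    u_itp = RegularGridInterpolator(
        (grid.xf, grid.yc), vel.u, bounds_error=False, fill_value=None
    )
    v_itp = RegularGridInterpolator(
        (grid.xc, grid.yf), vel.v, bounds_error=False, fill_value=None
    )
    umax = vel.max_speed
    if umax == 0:
        return [np.asarray([p]) for p in seed_points]

    def velocity(pt):
        return np.array([u_itp(pt)[0], v_itp(pt)[0]])

    def in_solid(pt):
        i = int((pt[0] - xmin) / grid.dx)
        j = int((pt[1] - ymin) / grid.dy)
        i = min(max(i, 0), grid.nx - 1)
        j = min(max(j, 0), grid.ny - 1)
        return not mask.fluid[i, j]

    def inside(pt):
        return xmin <= pt[0] <= xmax and ymin <= pt[1] <= ymax

    lines: list[np.ndarray] = []
    n_steps = int(max_len / step)
    for seed in np.atleast_2d(seed_points):
        pt = np.asarray(seed, float)
        if not inside(pt) or in_solid(pt):
            warnings.warn(f"streamline seed {tuple(seed)} lies in a solid; skipped")
            continue
        pts = [pt.copy()]
        for _ in range(n_steps):
            def rhs(q):
                w = velocity(q)
                s = np.hypot(*w)
                return w / s if s > 1e-12 * umax else np.zeros(2)

            k1 = rhs(pt)
            if not k1.any():
                break  # stagnation
            k2 = rhs(pt + 0.5 * step * k1)
            k3 = rhs(pt + 0.5 * step * k2)
            k4 = rhs(pt + step * k3)
            new = pt + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not inside(new) or in_solid(new):
                break
            pts.append(new)
            pt = new
        lines.append(np.asarray(pts))
    return lines
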