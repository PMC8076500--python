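"""Advection-diffusion core: face schemes, conservation, monotonicity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exotran.benchmark import all_fluid_mask
from exotran.errors import ConfigurationError
from exotran.flow import VelocityField
from exotran.geometry import GridSpec, build_grid
from exotran.transport import (
    SCHEMES,
    SourceSpec,
    TransportParams,
    TransportSolver,
    face_value,
    run_transport,
    total_mass,
    zero_velocity,
)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)


class TestFaceValue:
    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_uniform_stencil_is_consistent(self, scheme, sign):
        assert face_value([7.0, 7.0, 7.0, 7.0], sign, scheme) == pytest.approx(7.0)

    @pytest.mark.parametrize("scheme,expected", [
        ("upwind1", 2.0),
        ("upwind2", 2.5),
        ("quick", 2.5),  # quadratic reconstruction is exact on linear data
        ("muscl", 2.5),
    ])
    def test_linear_data_positive_velocity(self, scheme, expected):
        assert face_value([1.0, 2.0, 3.0], +1.0, scheme) == pytest.approx(expected)

    def test_negative_velocity_mirrors(self):
        # face between the first two values; upwind cell is the middle one
        assert face_value([3.0, 2.0, 1.0], -1.0, "upwind1") == pytest.approx(2.0)
        assert face_value([3.0, 2.0, 1.0], -1.0, "quick") == pytest.approx(2.5)

    @given(a=finite, b=finite, c=finite)
    def test_muscl_bounded_by_neighbors(self, a, b, c):
        f = face_value([a, b, c], +1.0, "muscl")
        assert min(b, c) - 1e-9 * max(1, abs(b), abs(c)) <= f
        assert f <= max(b, c) + 1e-9 * max(1, abs(b), abs(c))

    def test_local_extremum_muscl_falls_back_to_upwind(self):
        # (low, high, low): upwind cell is a maximum; limiter kills the slope
        assert face_value([0.0, 5.0, 0.0], +1.0, "muscl") == pytest.approx(5.0)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            face_value([1.0, 2.0, 3.0], 1.0, "weno5")

    def test_short_stencil_falls_back_to_upwind(self):
        assert face_value([1.0, 2.0], 1.0, "quick") == pytest.approx(1.0)


def make_uniform_velocity(grid, u):
    return VelocityField(
        np.full((grid.nx + 1, grid.ny), u), np.zeros((grid.nx, grid.ny + 1))
    )


class TestStep:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_constant_preserved_by_divergence_free_flow(self, scheme):
        from exotran.transport import Boundaries, BoundarySpec

        g = build_grid(GridSpec(nx=24, ny=24, dx=1.0, dy=1.0))
        mask = all_fluid_mask(g)
        vel = make_uniform_velocity(g, 0.3)
        params = TransportParams(gamma=1e-6, scheme=scheme, dt=1.0, t_end=10.0,
                                 integrator="explicit", cfl=1.0)
        bcs = Boundaries(left=BoundarySpec("dirichlet", 3.7),
                         right=BoundarySpec("outflow"))
        solver = TransportSolver(g, mask, params, velocity=vel, boundaries=bcs)
        c = np.full((24, 24), 3.7)
        c2 = solver.step(c, 0.0)
        assert np.allclose(c2, 3.7, rtol=1e-13)

    def test_single_cell_source_adds_exact_mass(self):
        g = build_grid(GridSpec(nx=8, ny=8, dx=0.5, dy=0.5, depth=2.0))
        mask = all_fluid_mask(g)
        region = np.zeros((8, 8), bool)
        region[4, 4] = True
        src = SourceSpec(total_rate=3.25, region=region)
        params = TransportParams(gamma=1e-9, dt=0.7, t_end=7.0)
        solver = TransportSolver(g, mask, params, sources=[src])
        c = np.zeros((8, 8))
        c2 = solver.step(c, 0.0)
        assert total_mass(c2, g, mask) == pytest.approx(3.25 * 0.7, rel=1e-12)

    def test_unit_cfl_upwind_translates_exactly(self):
        g = build_grid(GridSpec(nx=32, ny=4, dx=1.0, dy=1.0))
        mask = all_fluid_mask(g)
        vel = make_uniform_velocity(g, 1.0)
        params = TransportParams(gamma=1e-30, scheme="upwind1", dt=1.0,
                                 t_end=1.0, integrator="implicit", cfl=1.0)
        solver = TransportSolver(g, mask, params, velocity=vel)
        c = np.zeros((32, 4))
        c[10:14, :] = 1.0  # top hat away from boundaries
        c2 = solver.step(c, 0.0)
        assert np.allclose(c2, np.roll(c, 1, axis=0), atol=1e-12)

    def test_nan_detection(self):
        g = build_grid(GridSpec(nx=8, ny=8, dx=1.0, dy=1.0))
        mask = all_fluid_mask(g)
        params = TransportParams(gamma=1e-9, dt=1.0, t_end=1.0)
        solver = TransportSolver(g, mask, params)
        c = np.zeros((8, 8))
        c[3, 3] = np.nan
        from exotran.errors import NumericalError

        with pytest.raises(NumericalError):
            solver.step(c, 0.0)

    def test_explicit_stability_guard(self):
        g = build_grid(GridSpec(nx=8, ny=8, dx=1e-3, dy=1e-3))
        mask = all_fluid_mask(g)
        with pytest.raises(ConfigurationError, match="stability"):
            TransportSolver(
                g, mask,
                TransportParams(gamma=1e-3, dt=10.0, t_end=100.0,
                                integrator="explicit"),
            )


class TestRun:
    @pytest.mark.parametrize("integrator", ["implicit", "explicit"])
    def test_closed_domain_source_conservation(self, integrator):
        g = build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))
        mask = all_fluid_mask(g)
        region = np.zeros((16, 16), bool)
        region[8, 8] = True
        S, T = 2.0, 50.0
        params = TransportParams(gamma=1e-9, dt=0.5, t_end=T,
                                 integrator=integrator)
        hist = run_transport(
            np.zeros((16, 16)), None, params, [SourceSpec(S, region)], g, mask
        )
        assert hist.monitor("total_mass")[-1] == pytest.approx(S * T, rel=1e-10)

    def test_diffusion_variance_growth(self):
        # discrete Gaussian spreading: var(t) = var0 + 2*Gamma*t
        n, L, D = 96, 0.1, 1e-8
        g = build_grid(GridSpec(nx=n, ny=n, dx=L / n, dy=L / n,
                                origin=(-L / 2, -L / 2)))
        mask = all_fluid_mask(g)
        X, Y = g.centers()
        t0 = 1250.0  # 2*D*t0 = (5 mm)^2
        c0 = np.exp(-(X**2 + Y**2) / (4 * D * t0))
        params = TransportParams(gamma=D, dt=25.0, t_end=1250.0)
        hist = run_transport(c0, None, params, [], g, mask, n_checkpoints=1)
        c1 = hist.checkpoints[-1][1]

        def var_x(c):
            m = (c * g.cell_volume).sum()
            return ((X**2) * c * g.cell_volume).sum() / m

        assert var_x(c1) - var_x(c0) == pytest.approx(2 * D * 1250.0, rel=0.01)

    def test_source_linearity_superposition(self):
        g = build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))
        mask = all_fluid_mask(g)
        region = np.zeros((16, 16), bool)
        region[4, 9] = True
        params = TransportParams(gamma=1e-8, dt=1.0, t_end=20.0)

        def final(S):
            h = run_transport(np.zeros((16, 16)), None, params,
                              [SourceSpec(S, region)], g, mask, n_checkpoints=1)
            return h.checkpoints[-1][1]

        c1, c2 = final(1.5), final(3.0)
        assert np.allclose(c2, 2 * c1, rtol=1e-12, atol=1e-300)

    def test_upwind1_monotone_no_new_extrema(self, rng):
        from exotran.transport import Boundaries, BoundarySpec

        g = build_grid(GridSpec(nx=24, ny=24, dx=1.0, dy=1.0))
        mask = all_fluid_mask(g)
        vel = make_uniform_velocity(g, 0.4)
        params = TransportParams(gamma=1e-4, scheme="upwind1", dt=1.0,
                                 t_end=30.0, integrator="explicit", cfl=1.0)
        c0 = rng.uniform(0, 1, (24, 24))
        bcs = Boundaries(left=BoundarySpec("dirichlet", 0.0),
                         right=BoundarySpec("outflow"))
        hist = run_transport(c0, vel, params, [], g, mask,
                             boundaries=bcs, n_checkpoints=1)
        c1 = hist.checkpoints[-1][1]
        # no undershoot below the inflow value, no overshoot above the max
        assert c1.min() >= -1e-12
        assert c1.max() <= c0.max() + 1e-12


class TestTotalMass:
    def test_uniform_field(self):
        g = build_grid(GridSpec(nx=5, ny=4, dx=1.0, dy=1.0, depth=2.0))
        mask = all_fluid_mask(g)
        assert total_mass(np.ones((5, 4)), g, mask) == pytest.approx(40.0)

    def test_zero_field(self, small_grid, all_fluid):
        assert total_mass(np.zeros((16, 16)), small_grid, all_fluid) == 0.0

    def test_random_field_matches_bruteforce(self, small_grid, all_fluid, rng):
        c = rng.uniform(0, 5, (16, 16))
        brute = sum(
            c[i, j] * small_grid.cell_volume[i, j]
            for i in range(16) for j in range(16)
        )
        assert total_mass(c, small_grid, all_fluid) == pytest.approx(brute, rel=1e-12)

    def test_solid_cells_excluded(self, small_grid):
        from exotran.geometry import DomainMask

        fluid = np.ones((16, 16), bool)
        fluid[0:4, :] = False
        mask = DomainMask(fluid=fluid,
                          source_x=np.zeros((17, 16), bool),
                          source_y=np.zeros((16, 17), bool))
        c = np.ones((16, 16))
        assert total_mass(c, small_grid, mask) == pytest.approx(
            12 * 16 * small_grid.cell_volume[0, 0]
        )


class TestSourceSpec:
    def test_distribution_sums_exactly(self):
        g = build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))
        mask = all_fluid_mask(g)
        Q = SourceSpec(7.3, "bottom").cell_rates(g, mask)
        assert Q.sum() == pytest.approx(7.3, rel=1e-14)
        assert (Q[:, 1:] == 0).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SourceSpec(-1.0, "bottom")

    def test_tumor_faces_require_sources(self, small_grid, all_fluid):
        with pytest.raises(ConfigurationError):
            SourceSpec(1.0, "tumor_faces").cell_rates(small_grid, all_fluid)
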