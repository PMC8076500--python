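"""Stokes flow solver: analytic channel flow, obstacles, invariants."""

import numpy as np
import pytest

from exotran.benchmark import all_fluid_mask
from exotran.errors import ConfigurationError, GeometryError
from exotran.flow import (
    FlowBCs,
    FluidProps,
    compute_streamlines,
    divergence,
    mass_balance,
    reynolds_number,
    solve_flow,
)
from exotran.geometry import CellLayout, Circle, GridSpec, build_grid, rasterize_layout


def channel(nx, ny, L, H):
    return build_grid(GridSpec(nx=nx, ny=ny, dx=L / nx, dy=H / ny))


class TestReynolds:
    def test_interstitial_value_is_tiny(self):
        props = FluidProps(density=1000.0, viscosity=1e-3)
        re = reynolds_number(props, U=0.75e-6, L=1e-4)
        assert re == pytest.approx(7.5e-5)

    def test_zero_velocity(self):
        assert reynolds_number(FluidProps(), 0.0, 1e-4) == 0.0

    def test_linear_in_length(self):
        p = FluidProps()
        assert reynolds_number(p, 1e-6, 2e-4) == pytest.approx(
            2 * reynolds_number(p, 1e-6, 1e-4)
        )

    def test_bad_inputs(self):
        with pytest.raises(ConfigurationError):
            reynolds_number(FluidProps(), 1.0, 0.0)


class TestChannelFlow:
    def test_poiseuille_profile(self):
        # plug inlet develops into a parabola; sample near the outlet
        g = channel(96, 32, 4e-4, 1e-4)
        mask = all_fluid_mask(g)
        vel, _ = solve_flow(
            g, mask, FluidProps(), FlowBCs(inlet_velocity=0.75e-6, lateral="noslip")
        )
        prof = vel.u[84, :]
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=0.02)
        # analytic parabola shape
        y = g.yc / 1e-4
        para = 6 * prof.mean() * y * (1 - y)
        assert np.abs(prof - para).max() / prof.max() < 0.02

    def test_zero_inlet_gives_rest(self):
        g = channel(16, 8, 2e-4, 1e-4)
        vel, pres = solve_flow(
            g, all_fluid_mask(g), FluidProps(), FlowBCs(inlet_velocity=0.0)
        )
        assert np.abs(vel.u).max() == 0.0
        assert np.abs(pres.p).max() == 0.0

    def test_mass_balance_and_divergence(self):
        g = channel(48, 24, 4e-4, 2e-4)
        mask = all_fluid_mask(g)
        vel, _ = solve_flow(
            g, mask, FluidProps(), FlowBCs(inlet_velocity=0.75e-6, lateral="noslip")
        )
        qin, qout = mass_balance(g, mask, vel)
        assert abs(qin - qout) / qin < 1e-6
        assert np.abs(divergence(g, vel)[mask.fluid]).max() < 1e-8


@pytest.fixture(scope="module")
def obstacle_setup():
    g = channel(64, 32, 4e-4, 2e-4)
    lay = CellLayout(tumor=Circle(2e-4, 1e-4, 4e-5), extent=(0, 4e-4, 0, 2e-4))
    mask = rasterize_layout(lay, g)
    bcs = FlowBCs(inlet_velocity=0.75e-6, lateral="noslip")
    vel, pres = solve_flow(g, mask, FluidProps(), bcs)
    return g, mask, bcs, vel, pres


class TestObstacle:
    def test_solid_faces_are_noslip(self, obstacle_setup):
        g, mask, _, vel, _ = obstacle_setup
        solid = ~mask.fluid
        iu, ju = np.nonzero(solid)
        tol = 1e-12 * vel.max_speed
        assert np.abs(vel.u[iu, ju]).max() < tol
        assert np.abs(vel.u[iu + 1, ju]).max() < tol

    def test_pressure_drop_exceeds_open_channel(self, obstacle_setup):
        g, mask, bcs, _, pres = obstacle_setup
        open_mask = all_fluid_mask(g)
        _, p_open = solve_flow(g, open_mask, FluidProps(), bcs)

        def drop(p, m):
            return p.p[0][m.fluid[0]].mean() - p.p[-1][m.fluid[-1]].mean()

        assert drop(pres, mask) > drop(p_open, open_mask)

    def test_velocity_linear_in_inlet_speed(self, obstacle_setup):
        g, mask, bcs, vel, _ = obstacle_setup
        vel2, _ = solve_flow(
            g, mask, FluidProps(),
            FlowBCs(inlet_velocity=2 * bcs.inlet_velocity, lateral="noslip"),
        )
        assert np.allclose(vel2.u, 2 * vel.u, rtol=1e-10, atol=1e-18)

    def test_stokes_matches_navier_stokes_at_low_re(self, obstacle_setup):
        g, mask, bcs, vel, _ = obstacle_setup
        vel_ns, _ = solve_flow(g, mask, FluidProps(), bcs, include_inertia=True)
        scale = np.abs(vel.u).max()
        assert np.abs(vel_ns.u - vel.u).max() / scale < 1e-4

    def test_blocked_channel_raises(self):
        g = channel(32, 16, 4e-4, 2e-4)
        fluid = np.ones((32, 16), bool)
        fluid[16, :] = False  # full-height wall
        from exotran.geometry import DomainMask

        mask = DomainMask(
            fluid=fluid,
            source_x=np.zeros((33, 16), bool),
            source_y=np.zeros((32, 17), bool),
        )
        with pytest.raises(GeometryError):
            solve_flow(g, mask, FluidProps(), FlowBCs(inlet_velocity=1e-6))


class TestStreamlines:
    def test_uniform_flow_gives_straight_lines(self):
        g = channel(32, 16, 4e-4, 2e-4)
        mask = all_fluid_mask(g)
        vel, _ = solve_flow(g, mask, FluidProps(), FlowBCs(inlet_velocity=1e-6))
        seeds = np.array([[2e-5, 5e-5], [2e-5, 1.5e-4]])
        lines = compute_streamlines(g, mask, vel, seeds)
        for line, seed in zip(lines, seeds):
            assert len(line) > 10
            assert np.abs(line[:, 1] - seed[1]).max() < 1e-9

    def test_streamlines_avoid_solids(self, obstacle_setup):
        g, mask, _, vel, _ = obstacle_setup
        seeds = np.column_stack([
            np.full(8, 1e-5), np.linspace(2e-5, 1.8e-4, 8)
        ])
        for line in compute_streamlines(g, mask, vel, seeds):
            i = np.clip((line[:, 0] / g.dx).astype(int), 0, g.nx - 1)
            j = np.clip((line[:, 1] / g.dy).astype(int), 0, g.ny - 1)
            assert mask.fluid[i, j].all()

    def test_seed_in_solid_skipped_with_warning(self, obstacle_setup):
        g, mask, _, vel, _ = obstacle_setup
        with pytest.warns(UserWarning, match="solid"):
            lines = compute_streamlines(g, mask, vel, np.array([[2e-4, 1e-4]]))
        assert lines == []

    def test_tangency_to_velocity(self, obstacle_setup):
        # streamline segments must align with the local velocity direction
        from scipy.interpolate import RegularGridInterpolator

        g, mask, _, vel, _ = obstacle_setup
        u_itp = RegularGridInterpolator((g.xf, g.yc), vel.u, bounds_error=False,
                                        fill_value=None)
        v_itp = RegularGridInterpolator((g.xc, g.yf), vel.v, bounds_error=False,
                                        fill_value=None)
        lines = compute_streamlines(
            g, mask, vel, np.array([[1e-5, 0.7e-4]]), step=g.dx / 8
        )
        line = lines[0]
        mids = 0.5 * (line[:-1] + line[1:])
        seg = np.diff(line, axis=0)
        w = np.column_stack([u_itp(mids), v_itp(mids)])
        cosang = (seg * w).sum(1) / (
            np.linalg.norm(seg, axis=1) * np.linalg.norm(w, axis=1)
        )
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 5.0
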