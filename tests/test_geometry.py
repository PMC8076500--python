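"""Grids, rasterization, synthetic layouts, and image segmentation."""

import json

import numpy as np
import pytest

from exotran.errors import ConfigurationError, GeometryError, SegmentationError
from exotran.geometry import (
    CellLayout,
    Circle,
    Ellipse,
    GridSpec,
    build_grid,
    generate_tme_layout,
    rasterize_layout,
    render_layout,
    segment_image,
)


class TestBuildGrid:
    def test_benchmark_domain_centers(self):
        # 100 mm square, 200x200 cells, origin at the geometric center
        g = build_grid(
            GridSpec(nx=200, ny=200, dx=5e-4, dy=5e-4, origin=(-0.05, -0.05))
        )
        assert g.dx == g.dy == pytest.approx(5e-4)
        assert g.xc[0] == pytest.approx(-0.04975)
        assert g.yc[0] == pytest.approx(-0.04975)
        assert g.xf[-1] == pytest.approx(0.05)

    def test_total_volume_includes_depth(self):
        g = build_grid(GridSpec(nx=4, ny=4, dx=1.0, dy=1.0, depth=2.5))
        assert g.cell_volume.sum() == pytest.approx(16 * 2.5)

    def test_axisymmetric_volume_is_cylinder(self):
        R, H = 0.01, 0.004
        g = build_grid(
            GridSpec(nx=32, ny=8, dx=R / 32, dy=H / 8, coordinates="axisymmetric")
        )
        assert g.cell_volume.sum() == pytest.approx(np.pi * R**2 * H, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(nx=3, ny=8, dx=1.0, dy=1.0),
            dict(nx=8, ny=8, dx=-1.0, dy=1.0),
            dict(nx=8, ny=8, dx=1.0, dy=1.0, depth=0.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GridSpec(**kwargs)


class TestRasterize:
    def test_disk_area_consistency(self):
        g = build_grid(GridSpec(nx=64, ny=64, dx=1e-3, dy=1e-3))
        r = 10 * g.dx
        layout = CellLayout(tumor=Circle(0.032, 0.032, r))
        mask = rasterize_layout(layout, g)
        n_solid = (~mask.fluid).sum()
        assert n_solid == pytest.approx(np.pi * r**2 / (g.dx * g.dy), rel=0.05)

    def test_area_error_shrinks_under_refinement(self):
        errs = []
        for n in (32, 64, 128):
            g = build_grid(GridSpec(nx=n, ny=n, dx=64e-3 / n, dy=64e-3 / n))
            r = 0.01
            mask = rasterize_layout(CellLayout(tumor=Circle(0.032, 0.032, r)), g)
            area = (~mask.fluid).sum() * g.dx * g.dy
            errs.append(abs(area - np.pi * r**2) / (np.pi * r**2))
        assert errs[-1] < errs[0]

    def test_two_disjoint_circles_match_pointwise_oracle(self):
        g = build_grid(GridSpec(nx=48, ny=48, dx=1e-3, dy=1e-3))
        c1, c2 = Circle(0.012, 0.012, 0.005), Circle(0.036, 0.034, 0.007)
        layout = CellLayout(tumor=c1, immune=[])
        layout2 = CellLayout(tumor=c2, immune=[])
        both = CellLayout(
            tumor=c1,
            immune=[__import__("exotran.geometry", fromlist=["ImmuneCell"]).ImmuneCell(
                "macrophage", c2)],
        )
        n1 = (~rasterize_layout(layout, g).fluid).sum()
        n2 = (~rasterize_layout(layout2, g).fluid).sum()
        n_both = (~rasterize_layout(both, g).fluid).sum()
        assert n_both == n1 + n2
        # brute-force oracle: explicit point-in-shape test per center
        X, Y = g.centers()
        oracle = (c1.contains(X, Y) | c2.contains(X, Y)).sum()
        assert n_both == oracle

    def test_empty_layout_has_no_sources(self):
        g = build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))
        # tumor fully outside rasterization reach is not allowed; use a
        # tumor smaller than one cell instead (no centers inside)
        mask = rasterize_layout(CellLayout(tumor=Circle(1e-3, 1e-3, 1e-5)), g)
        assert mask.fluid.all()
        assert mask.n_source_faces == 0

    def test_source_faces_separate_fluid_from_tumor(self):
        g = build_grid(GridSpec(nx=32, ny=32, dx=1e-3, dy=1e-3))
        mask = rasterize_layout(CellLayout(tumor=Circle(0.016, 0.016, 0.006)), g)
        assert mask.n_source_faces > 0
        ix, jx = np.nonzero(mask.source_x[1:-1, :])
        assert np.all(mask.fluid[ix, jx] != mask.fluid[ix + 1, jx])

    def test_layout_outside_domain_rejected(self):
        g = build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))
        with pytest.raises(GeometryError):
            rasterize_layout(CellLayout(tumor=Circle(0.0, 0.0, 0.005)), g)


class TestGenerateLayout:
    def test_same_seed_identical(self):
        a = generate_tme_layout("early", 5, 8, 2, seed=1)
        b = generate_tme_layout("early", 5, 8, 2, seed=1)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_different_seed_differs(self):
        a = generate_tme_layout("early", 5, 8, 2, seed=1)
        b = generate_tme_layout("early", 5, 8, 2, seed=2)
        assert json.dumps(a.to_dict()) != json.dumps(b.to_dict())

    def test_late_tumor_area_ratio(self):
        e = generate_tme_layout("early", 0, 0, seed=3)
        l = generate_tme_layout("late", 0, 0, seed=3)
        assert l.tumor.area / e.tumor.area == pytest.approx(1.8**2)

    def test_tumor_only_layout_valid(self):
        lay = generate_tme_layout("early", 0, 0, seed=0)
        assert lay.immune == []

    def test_no_overlaps(self):
        lay = generate_tme_layout("late", 12, 20, 6, seed=7)
        shapes = [lay.tumor] + [c.shape for c in lay.immune]
        for i, a in enumerate(shapes):
            for b in shapes[i + 1:]:
                d = np.hypot(a.cx - b.cx, a.cy - b.cy)
                assert d >= a.r + b.r

    def test_impossible_packing_raises(self):
        from exotran.errors import PlacementError

        with pytest.raises(PlacementError):
            generate_tme_layout(
                "early", 500, 0, seed=0, extent=(0, 1e-4, 0, 1e-4),
                tumor_radius_early=3e-5, max_tries=50,
            )

    def test_counts_must_be_nonnegative(self):
        with pytest.raises(ConfigurationError):
            generate_tme_layout("early", -1, 0, seed=0)


class TestSegmentation:
    def test_single_disk_area(self):
        img = np.zeros((256, 256), np.uint8)
        yy, xx = np.mgrid[:256, :256]
        img[(xx - 128) ** 2 + (yy - 128) ** 2 < 50**2] = 255
        layout = segment_image(img, sigma=1.0)
        assert layout.tumor.area == pytest.approx(np.pi * 50**2, rel=0.03)

    def test_blank_image_raises(self):
        with pytest.raises(SegmentationError):
            segment_image(np.zeros((64, 64)))

    def test_disk_plus_small_circles_classified(self):
        img = np.zeros((256, 256), np.uint8)
        yy, xx = np.mgrid[:256, :256]
        img[(xx - 90) ** 2 + (yy - 90) ** 2 < 40**2] = 255
        for cx, cy in [(200, 60), (60, 200), (200, 200)]:
            img[(xx - cx) ** 2 + (yy - cy) ** 2 < 8**2] = 255
        layout = segment_image(img)
        assert len(layout.immune) == 3
        assert layout.tumor.area > max(np.pi * c.shape.r**2 for c in layout.immune)

    def test_render_segment_round_trip(self):
        scale = 1e-6  # 1 um per px
        truth = CellLayout(
            tumor=Ellipse(120e-6, 130e-6, 45e-6, 30e-6),
            immune=[],
            extent=(0, 256e-6, 0, 256e-6),
        )
        img = render_layout(truth, (256, 256), scale)
        rec = segment_image(img, sigma=1.0, scale=scale)
        assert rec.tumor.area == pytest.approx(truth.tumor.area, rel=0.05)
        v = rec.tumor.vertices
        cx, cy = v[:, 0].mean(), v[:, 1].mean()
        assert abs(cx - truth.tumor.cx) < 2 * scale
        assert abs(cy - truth.tumor.cy) < 2 * scale


class TestLayoutSerialization:
    def test_json_round_trip(self):
        lay = generate_tme_layout("late", 3, 4, 1, seed=9)
        rec = CellLayout.from_dict(json.loads(json.dumps(lay.to_dict())))
        assert json.dumps(rec.to_dict()) == json.dumps(lay.to_dict())
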