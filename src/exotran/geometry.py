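"""Computational geometry: Cartesian grids, cell layouts, masks, segmentation.

The tissue region is discretized on a uniform, cell-centered Cartesian grid.
Tumor and immune cells are represented as closed shapes (circles, ellipses,
polygons) that are rasterized into a fluid/solid mask by a cell-center
point-in-shape test (blocked-cell method, no cut cells).  Faces separating
fluid cells from tumor solid cells are flagged as exosome release (SOURCE)
faces; the total release rate is later distributed over those faces so the
prescribed rate is honored exactly regardless of rasterization error.

Axes: x rightward, y upward; 0-based indices; arrays indexed ``[i, j]`` with
``i`` along x.  For axisymmetric grids x plays the role of r and y of z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, GeometryError, PlacementError, SegmentationError

__all__ = [
    "GridSpec",
    "Grid",
    "build_grid",
    "Circle",
    "Ellipse",
    "Polygon",
    "ImmuneCell",
    "CellLayout",
    "DomainMask",
    "rasterize_layout",
    "generate_tme_layout",
    "segment_image",
    "render_layout",
    "IMMUNE_RADII",
]

MIN_CELLS = 4

# Default immune-cell radii (m); order-of-magnitude values for murine
# macrophages, T cells and myeloid-derived suppressor cells.
IMMUNE_RADII = {"macrophage": 10e-6, "tcell": 6e-6, "mdsc": 8e-6}


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian (or axisymmetric r-z) grid specification.

    Parameters
    ----------
    nx, ny : int
        Cell counts along x (or r) and y (or z); at least 4 each.
    dx, dy : float
        Cell sizes (m).
    origin : tuple of float
        Coordinates of the domain lower-left corner (m).
    depth : float
        Out-of-plane thickness used to convert 2-D concentrations to
        absolute exosome counts (m).  Ignored for axisymmetric grids where
        cell volumes are bodies of revolution.
    coordinates : {"cartesian", "axisymmetric"}
        Axisymmetric grids interpret x as radius r (origin[0] must be >= 0).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)
    depth: float = 1.0
    coordinates: Literal["cartesian", "axisymmetric"] = "cartesian"

    def __post_init__(self):
        if self.nx < MIN_CELLS or self.ny < MIN_CELLS:
            raise ConfigurationError(
                f"grid must be at least {MIN_CELLS}x{MIN_CELLS} cells, "
                f"got {self.nx}x{self.ny}"
            )
        if self.dx <= 0 or self.dy <= 0 or self.depth <= 0:
            raise ConfigurationError("dx, dy and depth must be positive")
        if self.coordinates == "axisymmetric" and self.origin[0] < 0:
            raise ConfigurationError("axisymmetric grid requires origin r >= 0")


@dataclass(frozen=True)
class Grid:
    """Realized grid: coordinates, face areas and cell volumes.

    ``face_area_x[i, j]`` is the area of the face normal to x between cells
    ``(i-1, j)`` and ``(i, j)``; similarly for y.  Volumes and areas include
    the out-of-plane depth (Cartesian) or the 2*pi*r revolution factor
    (axisymmetric), so integrals of concentration over cells are absolute
    exosome counts.
    """

    spec: GridSpec
    xc: np.ndarray  # (nx,) cell-center x
    yc: np.ndarray  # (ny,)
    xf: np.ndarray  # (nx+1,) face x
    yf: np.ndarray  # (ny+1,)
    cell_volume: np.ndarray  # (nx, ny)
    face_area_x: np.ndarray  # (nx+1, ny)
    face_area_y: np.ndarray  # (nx, ny+1)

    @property
    def nx(self) -> int:
        return self.spec.nx

    @property
    def ny(self) -> int:
        return self.spec.ny

    @property
    def dx(self) -> float:
        return self.spec.dx

    @property
    def dy(self) -> float:
        return self.spec.dy

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the domain (m)."""
        return self.xf[0], self.xf[-1], self.yf[0], self.yf[-1]

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (indexing='ij') of cell-center coordinates."""
        return np.meshgrid(self.xc, self.yc, indexing="ij")


def build_grid(spec: GridSpec) -> Grid:
    """Build cell-center/face coordinate arrays and metric arrays."""
    x0, y0 = spec.origin
    xf = x0 + spec.dx * np.arange(spec.nx + 1)
    yf = y0 + spec.dy * np.arange(spec.ny + 1)
    xc = 0.5 * (xf[:-1] + xf[1:])
    yc = 0.5 * (yf[:-1] + yf[1:])
    if spec.coordinates == "cartesian":
        vol = np.full((spec.nx, spec.ny), spec.dx * spec.dy * spec.depth)
        ax = np.full((spec.nx + 1, spec.ny), spec.dy * spec.depth)
        ay = np.full((spec.nx, spec.ny + 1), spec.dx * spec.depth)
    else:
        # body of revolution about x=0: x is radius r
        r_c = xc[:, None]
        r_f = xf[:, None]
        vol = np.broadcast_to(2 * np.pi * r_c * spec.dx * spec.dy, (spec.nx, spec.ny)).copy()
        ax = np.broadcast_to(2 * np.pi * r_f * spec.dy, (spec.nx + 1, spec.ny)).copy()
        ay = np.broadcast_to(2 * np.pi * r_c * spec.dx, (spec.nx, spec.ny + 1)).copy()
    return Grid(spec, xc, yc, xf, yf, vol, ax, ay)


# ---------------------------------------------------------------------------
# Shapes and layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 < self.r**2

    @property
    def area(self) -> float:
        return np.pi * self.r**2

    def bounds(self):
        return self.cx - self.r, self.cx + self.r, self.cy - self.r, self.cy + self.r


@dataclass(frozen=True)
class Ellipse:
    cx: float
    cy: float
    a: float  # semi-axis along x
    b: float  # semi-axis along y

    def contains(self, x, y):
        return ((x - self.cx) / self.a) ** 2 + ((y - self.cy) / self.b) ** 2 < 1.0

    @property
    def area(self) -> float:
        return np.pi * self.a * self.b

    def bounds(self):
        return self.cx - self.a, self.cx + self.a, self.cy - self.b, self.cy + self.b


@dataclass(frozen=True)
class Polygon:
    """Closed polygon given by an (n, 2) vertex array (m)."""

    vertices: np.ndarray

    def contains(self, x, y):
        from matplotlib.path import Path

        pts = np.column_stack([np.ravel(x), np.ravel(y)])
        inside = Path(self.vertices).contains_points(pts)
        return inside.reshape(np.shape(x))

    @property
    def area(self) -> float:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def bounds(self):
        v = self.vertices
        return v[:, 0].min(), v[:, 0].max(), v[:, 1].min(), v[:, 1].max()


Shape = Circle | Ellipse | Polygon


@dataclass(frozen=True)
class ImmuneCell:
    kind: Literal["macrophage", "tcell", "mdsc"]
    shape: Circle


@dataclass
class CellLayout:
    """Tumor plus immune cells inside a rectangular tissue domain.

    ``extent`` is (xmin, xmax, ymin, ymax) in meters; shapes must lie inside
    it and be pairwise non-overlapping.
    """

    tumor: Shape
    immune: list[ImmuneCell] = field(default_factory=list)
    stage: Literal["early", "late"] = "early"
    extent: tuple[float, float, float, float] | None = None

    def shapes(self) -> list[Shape]:
        return [self.tumor] + [c.shape for c in self.immune]

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(s: Shape) -> dict:
            if isinstance(s, Circle):
                return {"type": "circle", "cx": s.cx, "cy": s.cy, "r": s.r}
            if isinstance(s, Ellipse):
                return {"type": "ellipse", "cx": s.cx, "cy": s.cy, "a": s.a, "b": s.b}
            return {"type": "polygon", "vertices": np.asarray(s.vertices).tolist()}

        return {
            "stage": self.stage,
            "extent": list(self.extent) if self.extent else None,
            "tumor": enc(self.tumor),
            "immune": [{"kind": c.kind, **enc(c.shape)} for c in self.immune],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellLayout":
        def dec(s: dict) -> Shape:
            t = s["type"]
            if t == "circle":
                return Circle(s["cx"], s["cy"], s["r"])
            if t == "ellipse":
                return Ellipse(s["cx"], s["cy"], s["a"], s["b"])
            if t == "polygon":
                return Polygon(np.asarray(s["vertices"], float))
            raise ConfigurationError(f"unknown shape type {t!r}")

        immune = [ImmuneCell(c["kind"], dec(c)) for c in d.get("immune", [])]
        ext = d.get("extent")
        return cls(
            tumor=dec(d["tumor"]),
            immune=immune,
            stage=d.get("stage", "early"),
            extent=tuple(ext) if ext else None,
        )


@dataclass
class DomainMask:
    """Fluid/solid cell labels plus SOURCE face flags on a grid.

    ``fluid[i, j]`` is True for interstitial-fluid cells.  ``source_x`` /
    ``source_y`` flag faces on the tumor boundary (between a fluid cell and a
    tumor solid cell, or on the domain boundary for boundary-flux sources).
    ``membrane_y`` optionally marks a horizontal monitoring plane: the j-index
    of the y-face row used for flux counting, with ``membrane_cols`` the
    i-range it spans.
    """

    fluid: np.ndarray  # (nx, ny) bool
    source_x: np.ndarray  # (nx+1, ny) bool
    source_y: np.ndarray  # (nx, ny+1) bool
    tumor: np.ndarray | None = None  # (nx, ny) bool, solid cells that are tumor
    membrane_j: int | None = None
    membrane_cols: slice | None = None

    def __post_init__(self):
        if not self.fluid.any():
            raise GeometryError("mask has no FLUID cells")

    @property
    def n_source_faces(self) -> int:
        return int(self.source_x.sum() + self.source_y.sum())

    def source_face_areas(self, grid: Grid) -> float:
        """Total area of all SOURCE faces (m^2, including depth/revolution)."""
        return float(
            grid.face_area_x[self.source_x].sum() + grid.face_area_y[self.source_y].sum()
        )


def rasterize_layout(layout: CellLayout, grid: Grid) -> DomainMask:
    """Rasterize shapes to a fluid/solid mask; flag tumor-boundary SOURCE faces.

    A cell is SOLID iff its center lies inside any shape.  Faces between a
    FLUID cell and a tumor SOLID cell are SOURCE faces.
    """
    xmin, xmax, ymin, ymax = grid.extent
    for s in layout.shapes():
        bx0, bx1, by0, by1 = s.bounds()
        if bx0 < xmin or bx1 > xmax or by0 < ymin or by1 > ymax:
            raise GeometryError(f"shape {s} extends outside the domain {grid.extent}")
    X, Y = grid.centers()
    tumor = layout.tumor.contains(X, Y)
    solid = tumor.copy()
    for cell in layout.immune:
        solid |= cell.shape.contains(X, Y)
    fluid = ~solid

    nx, ny = grid.nx, grid.ny
    source_x = np.zeros((nx + 1, ny), bool)
    source_y = np.zeros((nx, ny + 1), bool)
    # interior x-faces between fluid and tumor
    source_x[1:nx, :] = (fluid[:-1, :] & tumor[1:, :]) | (tumor[:-1, :] & fluid[1:, :])
    source_y[:, 1:ny] = (fluid[:, :-1] & tumor[:, 1:]) | (tumor[:, :-1] & fluid[:, 1:])
    return DomainMask(fluid=fluid, source_x=source_x, source_y=source_y, tumor=tumor)


# ---------------------------------------------------------------------------
# Synthetic TME layout generation
# ---------------------------------------------------------------------------

def generate_tme_layout(
    stage: Literal["early", "late"],
    n_macrophages: int,
    n_tcells: int,
    n_mdscs: int = 0,
    seed: int = 0,
    extent: tuple[float, float, float, float] = (0.0, 1e-3, 0.0, 1e-3),
    tumor_radius_early: float = 100e-6,
    late_scale: float = 1.8,
    margin: float = 5e-6,
    max_tries: int = 2000,
) -> CellLayout:
    """Generate a reproducible synthetic tumor-microenvironment layout.

    The tumor is a circle at the domain center; the late stage scales its
    radius by ``late_scale`` (default 1.8, i.e. 3.24x area).  Immune cells
    (macrophages, T cells, MDSCs) are placed uniformly at random without
    overlap, keeping ``margin`` clearance from the tumor, each other and the
    domain boundary.  Identical (stage, counts, seed) give identical layouts.
    """
    if stage not in ("early", "late"):
        raise ConfigurationError(f"stage must be 'early' or 'late', got {stage!r}")
    if min(n_macrophages, n_tcells, n_mdscs) < 0:
        raise ConfigurationError("immune cell counts must be >= 0")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = extent
    cx, cy = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    r_tumor = tumor_radius_early * (late_scale if stage == "late" else 1.0)
    tumor = Circle(cx, cy, r_tumor)

    placed: list[Circle] = []
    kinds = (
        ["macrophage"] * n_macrophages + ["tcell"] * n_tcells + ["mdsc"] * n_mdscs
    )
    immune: list[ImmuneCell] = []
    for kind in kinds:
        r = IMMUNE_RADII[kind]
        for _ in range(max_tries):
            x = rng.uniform(xmin + r + margin, xmax - r - margin)
            y = rng.uniform(ymin + r + margin, ymax - r - margin)
            c = Circle(x, y, r)
            d_tumor = np.hypot(x - cx, y - cy)
            if d_tumor < r_tumor + r + margin:
                continue
            if all(
                np.hypot(x - o.cx, y - o.cy) >= r + o.r + margin for o in placed
            ):
                placed.append(c)
                immune.append(ImmuneCell(kind, c))
                break
        else:
            raise PlacementError(
                f"could not place a {kind} of radius {r:g} m after {max_tries} tries"
            )
    return CellLayout(tumor=tumor, immune=immune, stage=stage, extent=extent)


# ---------------------------------------------------------------------------
# Image segmentation
# ---------------------------------------------------------------------------

def segment_image(
    image: np.ndarray,
    sigma: float = 1.0,
    threshold: float | None = None,
    scale: float = 1.0,
    min_area_px: int = 9,
    kind_radius_thresholds: dict[str, float] | None = None,
) -> CellLayout:
    """Extract a cell layout from a raster image by edge/threshold segmentation.

    The image is smoothed (Gaussian, ``sigma`` px), thresholded (Otsu when
    ``threshold`` is None, on the convention that shapes are brighter than
    background after automatic polarity detection), and its connected
    components are extracted.  Each component's outer contour becomes a
    closed polygon; the largest component is labeled the tumor and the rest
    become circular immune cells of equivalent radius, classified by
    ``kind_radius_thresholds`` (a mapping kind -> max radius in meters,
    checked in increasing order; default: everything is a macrophage).

    ``scale`` converts pixel units to meters.  Image rows map to y (row 0 at
    y=0) and columns to x.
    """
    from skimage import filters, measure

    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise SegmentationError(f"expected a 2-D image, got shape {image.shape}")
    smooth = filters.gaussian(img, sigma=sigma, preserve_range=True)
    if smooth.max() == smooth.min():
        raise SegmentationError("image is constant; nothing to segment")
    thr = filters.threshold_otsu(smooth) if threshold is None else threshold
    binary = smooth > thr
    # shapes are the minority phase; flip polarity if needed
    if binary.mean() > 0.5:
        binary = ~binary
    labels = measure.label(binary)
    regions = [r for r in measure.regionprops(labels) if r.area >= min_area_px]
    if not regions:
        raise SegmentationError(
            f"no connected components above {min_area_px} px found "
            f"(threshold {thr:.4g}; check polarity and sigma)"
        )
    regions.sort(key=lambda r: r.area, reverse=True)

    def contour_polygon(region) -> Polygon:
        comp = labels == region.label
        cs = measure.find_contours(comp.astype(float), 0.5)
        contour = max(cs, key=len)  # outer boundary
        # rows -> y, cols -> x; +0.5 centers pixels
        verts = np.column_stack([(contour[:, 1] + 0.5), (contour[:, 0] + 0.5)]) * scale
        return Polygon(verts)

    tumor = contour_polygon(regions[0])
    immune: list[ImmuneCell] = []
    for reg in regions[1:]:
        cyx = reg.centroid
        r_eq = np.sqrt(reg.area / np.pi) * scale
        kind = "macrophage"
        if kind_radius_thresholds:
            for k, rmax in sorted(kind_radius_thresholds.items(), key=lambda kv: kv[1]):
                if r_eq <= rmax:
                    kind = k
                    break
        immune.append(
            ImmuneCell(kind, Circle((cyx[1] + 0.5) * scale, (cyx[0] + 0.5) * scale, r_eq))
        )
    ny_px, nx_px = img.shape
    return CellLayout(
        tumor=tumor,
        immune=immune,
        extent=(0.0, nx_px * scale, 0.0, ny_px * scale),
    )


def render_layout(
    layout: CellLayout, shape_px: tuple[int, int], scale: float
) -> np.ndarray:
    """Render a layout to a synthetic uint8 image (shapes 255 on 0 background).

    Inverse of :func:`segment_image` up to rasterization; used to test the
    segmentation round trip on known ground truth.
    """
    ny_px, nx_px = shape_px
    cols = (np.arange(nx_px) + 0.5) * scale
    rows = (np.arange(ny_px) + 0.5) * scale
    X, Y = np.meshgrid(cols, rows)  # row-major image
    img = np.zeros(shape_px, np.uint8)
    for s in layout.shapes():
        img[s.contains(X, Y)] = 255
    return img
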