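"""Planar polygon geometry and 2D shape descriptors for lesion contours.

A lesion is represented by a single closed contour on the axial slice of
maximum diameter, in physical millimetres.  The two descriptors of interest
are

* **solidity** — area divided by convex-hull area; 1.0 for any convex shape,
  lower when the boundary has protuberances or depressions;
* **circularity** — ``4*pi*area / perimeter**2``; 1.0 for a perfect circle,
  approaching 0 for elongated or very irregular shapes.

Both are dimensionless and invariant under rigid motions and uniform
scaling.  All geometry here is exact polygonal geometry: areas by the
shoelace formula, perimeters as sums of Euclidean edge lengths (including
the closing edge), convex hulls by the monotone-chain algorithm with strict
turns.  Binary masks enter through a sub-pixel marching-squares boundary
(iso-level 0.5, pixel-centre coordinates) so that the isoperimetric bound
``4*pi*A <= P**2`` holds exactly for every extracted contour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import measure as _sk_measure
from skimage.draw import polygon as _sk_draw_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "Contour",
    "BinaryMask",
    "ShapeFeatures",
    "polygon_area",
    "polygon_perimeter",
    "convex_hull",
    "mask_to_contour",
    "rasterize_contour",
    "shape_features",
]


class GeometryError(ValueError):
    """Invalid or degenerate geometry (self-intersection, collinearity, ...)."""


def _as_vertex_array(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise GeometryError(f"vertices must be an (n, 2) array, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError("vertices contain non-finite coordinates")
    return v


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon (ordered vertices, mm); the last vertex connects
    back to the first implicitly.

    On construction the vertex list is validated (>= 3 vertices, no repeated
    consecutive vertices, simple) and the orientation is normalised to
    counter-clockwise.  An explicitly repeated closing vertex is stripped.
    """

    vertices: np.ndarray

    def __init__(self, vertices) -> None:
        v = _as_vertex_array(vertices)
        # tolerate an explicit closing vertex (common in CSV exports)
        if len(v) >= 2 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise GeometryError(f"a contour needs at least 3 vertices, got {len(v)}")
        dup = np.all(v == np.roll(v, -1, axis=0), axis=1)
        if np.any(dup):
            raise GeometryError("contour has identical consecutive vertices")
        sa = _signed_area(v)
        if abs(sa) == 0.0:
            raise GeometryError("contour is degenerate (zero area)")
        if not _ShapelyPolygon(v).is_valid:
            raise GeometryError("contour is self-intersecting or otherwise invalid")
        if sa < 0:  # normalise to counter-clockwise
            v = v[::-1]
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    def transformed(self, *, scale: float = 1.0, angle: float = 0.0,
                    shift=(0.0, 0.0)) -> "Contour":
        """Similarity transform (uniform scale, rotation, translation)."""
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return Contour(scale * self.vertices @ rot.T + np.asarray(shift, float))


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean foreground mask with physical pixel spacing (row_mm, col_mm)."""

    grid: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise GeometryError(f"mask grid must be 2D, got {g.ndim}D")
        if not g.any():
            raise GeometryError("mask has no foreground pixels")
        sp = (float(self.spacing[0]), float(self.spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise GeometryError(f"pixel spacing must be positive, got {sp}")
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "spacing", sp)


@dataclass(frozen=True)
class ShapeFeatures:
    """Shape descriptors of one contour.

    ``circularity`` is capped at 1.0 (digital-contour convention); the
    uncapped value is kept in ``circularity_raw``.  ``max_diameter`` is the
    maximum Feret (caliper) diameter, the 2D analogue of the RECIST longest
    diameter.
    """

    area: float          # mm^2
    perimeter: float     # mm
    hull_area: float     # mm^2
    solidity: float
    circularity: float
    max_diameter: float  # mm
    circularity_raw: float = field(repr=False, default=float("nan"))


def polygon_area(contour: Contour) -> float:
    """Enclosed area in mm^2 (absolute shoelace sum; orientation-independent)."""
    return abs(_signed_area(contour.vertices))


def polygon_perimeter(contour: Contour) -> float:
    """Boundary length in mm, including the closing edge."""
    v = contour.vertices
    return float(np.sum(np.hypot(*(np.roll(v, -1, axis=0) - v).T)))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> Contour:
    """Convex hull of a planar point set as a counter-clockwise Contour.

    Monotone-chain with strict turns: collinear boundary points are dropped,
    so the hull of a convex polygon returns exactly its vertex set.  Raises
    :class:`GeometryError` if all points are collinear.
    """
    pts_arr = _as_vertex_array(points)
    pts_arr = np.unique(pts_arr, axis=0)  # lexicographic sort by x, then y
    if len(pts_arr) < 3:
        raise GeometryError("convex hull needs at least 3 distinct points")
    pts = [(float(x), float(y)) for x, y in pts_arr]

    def half(chain_pts):
        out: list[tuple[float, float]] = []
        for p in chain_pts:
            while len(out) >= 2 and _cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        raise GeometryError("all points are collinear; hull is degenerate")
    return Contour(np.array(hull))


def _smooth_ring(ring: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of a closed vertex ring.

    Marching squares on a binary image yields a staircase boundary whose
    length overestimates the true perimeter by several percent regardless of
    resolution; averaging over a few boundary vertices removes that bias
    (the window is in pixels, so the induced rounding of real corners
    vanishes as resolution grows).  Rings too short for the window are
    returned unchanged.
    """
    n = len(ring)
    w = min(window, max(1, n // 4))
    if w < 2:
        return ring
    kern = np.ones(w) / w
    ext = np.vstack([ring[-(w // 2):], ring, ring[: w - 1 - (w // 2)]])
    return np.column_stack([
        np.convolve(ext[:, 0], kern, "valid"),
        np.convolve(ext[:, 1], kern, "valid"),
    ])


def mask_to_contour(mask: BinaryMask, smooth_window: int = 5) -> Contour:
    """Sub-pixel boundary (mm) of the largest foreground component.

    Uses marching squares at iso-level 0.5 on the zero-padded mask, so the
    boundary passes midway between foreground and background pixel centres,
    followed by a short moving-average smoothing of the staircase (see
    :func:`_smooth_ring`; ``smooth_window=1`` disables it).  Multiple
    connected components trigger a warning; the largest (by pixel count) is
    kept, matching a single-target-lesion segmentation.
    """
    labels, n_comp = _sk_measure.label(mask.grid, return_num=True, connectivity=1)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        warnings.warn(
            f"mask has {n_comp} connected components; keeping the largest "
            f"({sizes[keep - 1]} px), ignoring {int(sizes.sum() - sizes[keep - 1])} px",
            stacklevel=2,
        )
        grid = labels == keep
    else:
        grid = mask.grid
    padded = np.pad(grid.astype(float), 1)
    rings = _sk_measure.find_contours(padded, level=0.5)
    if not rings:  # unreachable given the BinaryMask invariant
        raise GeometryError("no iso-contour found in mask")

    def ring_area(r):
        x, y = r[:, 1], r[:, 0]
        return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    ring = max(rings, key=ring_area)  # outer boundary, not holes
    if np.array_equal(ring[0], ring[-1]):
        ring = ring[:-1]
    ring = _smooth_ring(ring, smooth_window)
    row_mm, col_mm = mask.spacing
    xy = np.column_stack([(ring[:, 1] - 1.0) * col_mm, (ring[:, 0] - 1.0) * row_mm])
    return Contour(xy)


def rasterize_contour(contour: Contour, pixel_mm: float = 1.0) -> BinaryMask:
    """Rasterize a contour to a pixel-centre binary mask at the given spacing.

    A pixel is foreground when its centre lies inside the polygon.  Mainly
    used to exercise the mask ingestion path against known analytic shapes.
    """
    if pixel_mm <= 0:
        raise GeometryError("pixel size must be positive")
    v = contour.vertices / pixel_mm
    lo = np.floor(v.min(axis=0)) - 2
    cols = v[:, 0] - lo[0]
    rows = v[:, 1] - lo[1]
    shape = (int(np.ceil(rows.max())) + 3, int(np.ceil(cols.max())) + 3)
    rr, cc = _sk_draw_polygon(rows, cols, shape=shape)
    grid = np.zeros(shape, dtype=bool)
    grid[rr, cc] = True
    return BinaryMask(grid, (pixel_mm, pixel_mm))


def _max_feret(hull_vertices: np.ndarray) -> float:
    # exhaustive over hull vertices; hulls of lesion contours are small
    d2 = np.sum((hull_vertices[:, None, :] - hull_vertices[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(contour: Contour) -> ShapeFeatures:
    """Compute all shape descriptors of one contour.

    circularity = 4*pi*area / perimeter**2, capped at 1.0 (raw value kept);
    solidity = area / convex-hull area; max_diameter = maximum pairwise
    distance between hull vertices.
    """
    area = polygon_area(contour)
    perim = polygon_perimeter(contour)
    hull = convex_hull(contour.vertices)
    hull_area = polygon_area(hull)
    # mathematically area <= hull_area; guard against rounding noise only
    solidity = min(area / hull_area, 1.0)
    circ_raw = 4.0 * np.pi * area / perim**2
    circ = circ_raw
    if circ_raw > 1.0:
        logger.warning("raw circularity %.6g exceeds 1.0; capping", circ_raw)
        circ = 1.0
    return ShapeFeatures(
        area=area,
        perimeter=perim,
        hull_area=hull_area,
        solidity=solidity,
        circularity=circ,
        max_diameter=_max_feret(hull.vertices),
        circularity_raw=circ_raw,
    )
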