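"""Wound-edge band statistics and migration-distance measurement.

Healing epithelium is scored by counting marker-positive cells (Ki67,
EdU, pERK1/2, ...) inside a fixed-width band of the wound margin —
conventionally the cells within 100 µm of the edge — and, in debridement
wounds, by measuring how far the epithelial front has advanced from the
original wound edge.

Geometry is continuous 2-D Cartesian in µm. Wound edges are simple
polylines; distances are minimum Euclidean point-to-polyline distances
(perpendicular foot or nearest endpoint). When coordinates derive from
image masks, the origin is the image top-left with y increasing downward
and positions are connected-component area centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .errors import InvalidInputError

__all__ = [
    "CellRecord",
    "EdgeGeometry",
    "BandCount",
    "MigrationResult",
    "distance_to_polyline",
    "distances_to_polyline",
    "band_fraction",
    "migration_distance",
    "centroids_from_mask",
]


@dataclass(frozen=True)
class CellRecord:
    """A marker-scored cell centroid in µm image coordinates."""

    image_id: str
    x: float
    y: float
    marker: str
    positive: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError("cell coordinates must be finite")
        if not self.marker:
            raise InvalidInputError("marker label must be non-empty")


@dataclass(frozen=True)
class EdgeGeometry:
    """A wound-edge polyline (original scratch edge or migrating front)."""

    image_id: str
    edge_type: str  # "original" | "front"
    vertices: np.ndarray  # (n, 2) in µm

    def __post_init__(self) -> None:
        if self.edge_type not in ("original", "front"):
            raise InvalidInputError(f"unknown edge_type {self.edge_type!r}")
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidInputError("polyline needs >= 2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("polyline vertices must be finite")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise InvalidInputError("consecutive polyline vertices must be distinct")
        if not LineString(v).is_simple:
            raise InvalidInputError("polyline must not self-intersect")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length_um(self) -> float:
        return float(self.line.length)


@dataclass(frozen=True)
class BandCount:
    """Counts of (positive) cells within a distance band of a wound edge.

    ``fraction`` is ``n_positive / n_total``; with no cells in the band it
    is NaN (undefined), never zero.
    """

    band_um: float
    n_total: int
    n_positive: int
    fraction: float

    def __post_init__(self) -> None:
        if self.n_positive > self.n_total:
            raise InvalidInputError("n_positive cannot exceed n_total")


@dataclass(frozen=True)
class MigrationResult:
    """Per-sample front-to-original-edge distances with summary stats (µm)."""

    per_sample_distances: np.ndarray
    mean_um: float
    std_um: float


def distance_to_polyline(p: Sequence[float], edge: EdgeGeometry) -> float:
    """Minimum Euclidean distance (µm) from a point to the edge polyline."""
    return float(edge.line.distance(Point(float(p[0]), float(p[1]))))


def distances_to_polyline(points: np.ndarray, edge: EdgeGeometry) -> np.ndarray:
    """Vectorized minimum distances from an (n, 2) point array to the edge."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.zeros(0)
    return shapely.distance(shapely.points(pts), edge.line)


def band_fraction(
    cells: Sequence[CellRecord],
    edge: EdgeGeometry,
    band_um: float = 100.0,
    marker: Optional[str] = None,
) -> BandCount:
    """Positive-cell fraction within ``band_um`` of the wound edge.

    Band membership uses a closed boundary (distance <= band_um). If
    ``marker`` is given, only cells carrying that marker are considered.
    An empty band yields ``n_total = 0`` and a NaN fraction.
    """
    if band_um <= 0:
        raise InvalidInputError("band_um must be positive")
    if marker is not None:
        cells = [c for c in cells if c.marker == marker]
    if not cells:
        return BandCount(band_um=band_um, n_total=0, n_positive=0, fraction=math.nan)
    pts = np.array([[c.x, c.y] for c in cells], dtype=float)
    in_band = distances_to_polyline(pts, edge) <= band_um
    n_total = int(in_band.sum())
    n_pos = int(sum(1 for c, m in zip(cells, in_band) if m and c.positive))
    frac = n_pos / n_total if n_total > 0 else math.nan
    return BandCount(band_um=band_um, n_total=n_total, n_positive=n_pos, fraction=frac)


def migration_distance(
    original: EdgeGeometry, front: EdgeGeometry, n_samples: int = 50
) -> MigrationResult:
    """Epithelial migration between the original wound edge and the front.

    ``n_samples`` points are placed uniformly by arc length along the
    front polyline; each point's distance to the original edge is
    recorded. For a front that is a rigid translation of a straight
    original edge this reduces to the translation magnitude at every
    sample. Standard deviation uses the n-1 denominator.
    """
    if n_samples < 1:
        raise InvalidInputError("n_samples must be >= 1")
    line = front.line
    stations = np.linspace(0.0, line.length, n_samples)
    samples = shapely.line_interpolate_point(line, stations)
    d = shapely.distance(samples, original.line)
    mean = float(np.mean(d))
    std = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return MigrationResult(per_sample_distances=np.asarray(d), mean_um=mean, std_um=std)


def centroids_from_mask(
    mask: np.ndarray,
    pixel_size_um: float,
    image_id: str = "mask",
    marker: str = "cell",
    positive: bool = True,
    min_area_px: int = 4,
) -> List[CellRecord]:
    """Cell centroids from a binary label mask.

    Connected components (8-connectivity) with area >= ``min_area_px``
    become records at their area centroid, scaled by ``pixel_size_um``,
    ordered by (y, x). Sub-threshold blobs are treated as noise.
    """
    import skimage.measure

    m = np.asarray(mask)
    if m.ndim != 2:
        raise InvalidInputError("mask must be a 2-D image")
    if pixel_size_um <= 0:
        raise InvalidInputError("pixel_size_um must be positive")
    uniq = np.unique(m)
    if not np.all(np.isin(uniq, (0, 1))) and m.dtype != bool:
        raise InvalidInputError("mask must be binary (0/1 or bool)")
    labels = skimage.measure.label(m.astype(bool), connectivity=2)
    records = []
    for region in skimage.measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid  # (row, col)
        records.append(
            CellRecord(
                image_id=image_id,
                x=float(cx) * pixel_size_um,
                y=float(cy) * pixel_size_um,
                marker=marker,
                positive=positive,
            )
        )
    records.sort(key=lambda c: (c.y, c.x))
    return records
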