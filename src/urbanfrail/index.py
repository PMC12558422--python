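"""Urban-quality summary index: distance rasters, proximity scores, quartiles.

Pipeline: for each facility layer compute the exact Euclidean distance from
every cell center to the nearest facility point, reclassify the distance
surface into proximity scores 3/2/1 using the layer's bands, and sum the
score layers cellwise into the summary index (7 default layers -> values in
[7, 21], higher = better urban quality). The index is read off at participant
locations by cell containment (a spatial join, no interpolation), and
participants are stratified into empirical quartiles of their index values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .facilities import DistanceBands, FacilityLayer, FacilityType
from .grid import GridSpec, RasterField

logger = logging.getLogger(__name__)

QUARTILE_NAMES = ("Q1", "Q2", "Q3", "Q4")


def compute_distance_raster(grid: GridSpec, layer: FacilityLayer) -> RasterField:
    """Exact Euclidean distance (m) from each cell center to the nearest
    facility point of ``layer``.

    Uses a k-d tree, which returns exact (not approximate) nearest-neighbor
    distances; deterministic for fixed inputs.
    """
    if len(layer) < 1:
        raise ValueError("no facility points")
    cx, cy = grid.cell_centers()
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    d, _ = cKDTree(layer.points).query(centers, k=1)
    return RasterField(grid, d.reshape(grid.n_rows, grid.n_cols), kind="distance")


def classify_distance(d, bands: DistanceBands):
    """Reclassify distance(s) to the 3/2/1 proximity score.

    d < near_max -> 3 (close); near_max <= d <= mid_max -> 2 (medium);
    d > mid_max -> 1 (distant). Boundary distances score 2: the band tables
    are printed as strict inequalities on both outer zones.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    score = np.where(d < bands.near_max, 3, np.where(d > bands.mid_max, 1, 2))
    return score if score.ndim else int(score)


def score_raster(distance: RasterField, bands: DistanceBands) -> RasterField:
    """Reclassify a distance raster into a proximity-score raster."""
    if distance.kind != "distance":
        raise ValueError(f"expected a distance raster, got kind={distance.kind!r}")
    return RasterField(distance.grid, classify_distance(distance.values, bands), kind="score")


def facility_score_raster(grid: GridSpec, layer: FacilityLayer) -> RasterField:
    """Convenience: distance raster then reclassification for one layer."""
    return score_raster(compute_distance_raster(grid, layer), layer.bands)


def summary_index(
    score_rasters: list[RasterField],
    facility_types: list[FacilityType] | None = None,
) -> RasterField:
    """Cellwise sum of per-facility proximity-score rasters.

    All rasters must share one grid; when ``facility_types`` is given, each
    type may appear at most once. With n layers every cell lies in [n, 3n].
    """
    if not score_rasters:
        raise ValueError("need at least one score raster")
    grid = score_rasters[0].grid
    for r in score_rasters:
        if r.kind != "score":
            raise ValueError(f"expected score rasters, got kind={r.kind!r}")
        if r.grid != grid:
            raise ValueError("mismatched grids among score rasters")
    if facility_types is not None:
        if len(facility_types) != len(score_rasters):
            raise ValueError("facility_types length must match score_rasters")
        seen = [FacilityType(t) for t in facility_types]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate facility type among score rasters")
    total = np.sum([r.values for r in score_rasters], axis=0)
    return RasterField(grid, total, kind="index", n_layers=len(score_rasters))


def build_summary_index(grid: GridSpec, layers: list[FacilityLayer]) -> RasterField:
    """Full index construction from facility layers (one per type)."""
    rasters = [facility_score_raster(grid, lyr) for lyr in layers]
    return summary_index(rasters, [lyr.facility_type for lyr in layers])


def extract_index_at_points(index: RasterField, points, ids=None) -> np.ndarray:
    """Value of the cell containing each point (no interpolation).

    Cell extents are half-open, so edge points resolve deterministically.
    Points outside the grid raise, listing the offending point ids.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    grid = index.grid
    inside = grid.contains(pts[:, 0], pts[:, 1])
    if not np.all(inside):
        bad = np.nonzero(~inside)[0]
        labels = [str(ids[i]) if ids is not None else str(i) for i in bad]
        raise ValueError(f"points outside grid extent: {', '.join(labels)}")
    row, col = grid.cell_of(pts[:, 0], pts[:, 1])
    return index.values[row, col]


@dataclass
class QuartileAssignment:
    """Quartile label per value plus the empirical bin edges used."""

    labels: np.ndarray  # array of "Q1".."Q4"
    edges: tuple[float, float, float]  # 25/50/75 percentiles

    def members(self, q: str) -> np.ndarray:
        return np.nonzero(self.labels == q)[0]


def assign_quartiles(values) -> QuartileAssignment:
    """Stratify values into empirical quartiles.

    Edges are the 25/50/75 percentiles; bins are right-closed above Q1
    (Q1 = [min, e25], Qk = (e_{k-1}, e_k]), so tied values never straddle
    bins. With heavy ties some quartiles may be empty; all-equal input
    degenerates to everyone in Q1 (logged).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to form quartiles")
    e25, e50, e75 = np.percentile(v, [25, 50, 75])
    if e25 == e75:
        logger.warning("degenerate quartile edges (all values in one bin)")
    labels = np.full(v.shape, "Q1", dtype=object)
    labels[v > e25] = "Q2"
    labels[v > e50] = "Q3"
    labels[v > e75] = "Q4"
    return QuartileAssignment(labels=np.asarray(labels, dtype=object), edges=(e25, e50, e75))


def distance_to_nearest(points, layer: FacilityLayer) -> np.ndarray:
    """Exact Euclidean distance (m) from each point to its nearest facility.

    Unlike the raster surface this is measured from the points themselves,
    not from cell centers."""
    if len(layer) < 1:
        raise ValueError("no facility points")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d, _ = cKDTree(layer.points).query(pts, k=1)
    return d
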