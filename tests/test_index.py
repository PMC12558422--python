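"""Urban-quality geometry: distance rasters, reclassification, index,
extraction, quartiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from urbanfrail.facilities import DEFAULT_BANDS, DistanceBands, FacilityLayer, FacilityType
from urbanfrail.grid import GridSpec, RasterField
from urbanfrail.index import (
    assign_quartiles,
    build_summary_index,
    classify_distance,
    compute_distance_raster,
    distance_to_nearest,
    extract_index_at_points,
    facility_score_raster,
    summary_index,
)


def brute_force_distances(grid: GridSpec, points: np.ndarray) -> np.ndarray:
    """Independent oracle: exhaustive min-over-points Euclidean distance."""
    cx, cy = grid.cell_centers()
    d = np.full(cx.shape, np.inf)
    for px, py in points:
        d = np.minimum(d, np.sqrt((cx - px) ** 2 + (cy - py) ** 2))
    return d


def layer(points, ftype=FacilityType.pharmacies):
    return FacilityLayer(ftype, np.asarray(points, float))


class TestDistanceRaster:
    def test_coincident_point_gives_zero(self):
        grid = GridSpec(n_rows=1, n_cols=1, cell_size=50)
        r = compute_distance_raster(grid, layer([(25.0, 25.0)]))
        assert r.values[0, 0] == 0.0

    def test_axis_aligned_neighbor_cell(self):
        grid = GridSpec(n_rows=1, n_cols=2, cell_size=50)
        r = compute_distance_raster(grid, layer([(25.0, 25.0)]))
        np.testing.assert_allclose(r.values, [[0.0, 50.0]])

    @pytest.mark.parametrize("n_points", [1, 5, 20])
    def test_matches_brute_force_oracle_exactly(self, rng, n_points):
        grid = GridSpec(n_rows=20, n_cols=20, cell_size=50)
        pts = rng.uniform(0, 1000, size=(n_points, 2))
        r = compute_distance_raster(grid, layer(pts))
        np.testing.assert_array_equal(r.values, brute_force_distances(grid, pts))

    def test_empty_layer_rejected(self):
        with pytest.raises(ValueError, match="no facility points"):
            FacilityLayer(FacilityType.pharmacies, np.empty((0, 2)))


class TestClassifyDistance:
    @pytest.mark.parametrize(
        "d, ftype, expected",
        [
            (100, FacilityType.vegetables_fruits, 3),
            (300, FacilityType.vegetables_fruits, 2),  # boundary -> middle band
            (600, FacilityType.vegetables_fruits, 2),
            (601, FacilityType.vegetables_fruits, 1),
            (2500, FacilityType.emergency_health, 1),
            (0, FacilityType.squares_parks, 3),
        ],
    )
    def test_band_assignment(self, d, ftype, expected):
        assert classify_distance(d, DEFAULT_BANDS[ftype]) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_distance(-1.0, DistanceBands(300, 600))

    @given(st.lists(st.floats(0, 5000), min_size=2, max_size=20))
    def test_non_increasing_in_distance(self, ds):
        bands = DistanceBands(300, 600)
        ds = sorted(ds)
        scores = [classify_distance(d, bands) for d in ds]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestSummaryIndex:
    def test_seven_layer_extremes_and_additivity(self):
        grid = GridSpec(n_rows=2, n_cols=2)
        hi = [RasterField(grid, np.full((2, 2), 3), "score") for _ in range(7)]
        lo = [RasterField(grid, np.full((2, 2), 1), "score") for _ in range(7)]
        assert np.all(summary_index(hi).values == 21)
        assert np.all(summary_index(lo).values == 7)
        two = summary_index(
            [RasterField(grid, np.full((2, 2), 3), "score"),
             RasterField(grid, np.full((2, 2), 2), "score")]
        )
        assert np.all(two.values == 5)

    def test_mismatched_grids_rejected(self):
        a = RasterField(GridSpec(n_rows=2, n_cols=2), np.full((2, 2), 2), "score")
        b = RasterField(GridSpec(n_rows=2, n_cols=2, cell_size=10), np.full((2, 2), 2), "score")
        with pytest.raises(ValueError, match="mismatched grids"):
            summary_index([a, b])

    def test_duplicate_facility_type_rejected(self):
        grid = GridSpec(n_rows=2, n_cols=2)
        r = RasterField(grid, np.full((2, 2), 2), "score")
        with pytest.raises(ValueError, match="duplicate"):
            summary_index([r, r], [FacilityType.pharmacies, FacilityType.pharmacies])

    def test_seven_default_layers_bounded(self, rng):
        grid = GridSpec(n_rows=15, n_cols=15)
        layers = [
            FacilityLayer(t, rng.uniform(0, 750, (4, 2))) for t in FacilityType
        ]
        idx = build_summary_index(grid, layers)
        assert idx.values.min() >= 7 and idx.values.max() <= 21
        assert np.all(idx.values == np.round(idx.values))

    def test_adding_a_facility_never_lowers_scores(self, rng):
        grid = GridSpec(n_rows=12, n_cols=12)
        pts = rng.uniform(0, 600, (3, 2))
        extra = np.vstack([pts, rng.uniform(0, 600, (1, 2))])
        before = facility_score_raster(grid, layer(pts)).values
        after = facility_score_raster(grid, layer(extra)).values
        assert np.all(after >= before)


class TestExtractAtPoints:
    def test_cell_center_containment(self):
        grid = GridSpec(n_rows=2, n_cols=2, cell_size=50)
        vals = np.array([[17, 18], [19, 20]])
        idx = RasterField(grid, vals, "index", n_layers=7)
        assert extract_index_at_points(idx, [(75.0, 25.0)])[0] == 18

    def test_shared_edge_uses_half_open_cell(self):
        grid = GridSpec(n_rows=1, n_cols=2, cell_size=50)
        idx = RasterField(grid, np.array([[17, 18]]), "index", n_layers=7)
        # x = 50 lies on the shared edge -> right cell ([50, 100))
        assert extract_index_at_points(idx, [(50.0, 25.0)])[0] == 18

    def test_outside_point_reported_by_id(self):
        grid = GridSpec(n_rows=1, n_cols=1, cell_size=50)
        idx = RasterField(grid, np.array([[7]]), "index", n_layers=7)
        with pytest.raises(ValueError, match="P9"):
            extract_index_at_points(idx, [(25.0, 25.0), (500.0, 25.0)], ids=["P1", "P9"])

    def test_agrees_with_pointwise_recomputation(self, rng):
        """Raster extraction equals distance->classify->sum done directly at
        each point's cell center."""
        grid = GridSpec(n_rows=10, n_cols=10, cell_size=50)
        layers = [FacilityLayer(t, rng.uniform(0, 500, (3, 2))) for t in FacilityType]
        idx = build_summary_index(grid, layers)
        pts = rng.uniform(0, 500 - 1e-9, (100, 2))
        got = extract_index_at_points(idx, pts)
        row, col = grid.cell_of(pts[:, 0], pts[:, 1])
        centers = np.column_stack(
            [(col + 0.5) * grid.cell_size, (row + 0.5) * grid.cell_size]
        )
        expected = np.zeros(len(pts))
        for lyr in layers:
            d = np.min(
                np.hypot(
                    centers[:, None, 0] - lyr.points[None, :, 0],
                    centers[:, None, 1] - lyr.points[None, :, 1],
                ),
                axis=1,
            )
            expected += np.asarray(classify_distance(d, lyr.bands))
        np.testing.assert_array_equal(got, expected)


class TestQuartiles:
    def test_uniform_ranks_split_evenly(self):
        qa = assign_quartiles(np.arange(1, 9))
        assert list(qa.labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_all_equal_degenerates_to_q1(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            qa = assign_quartiles(np.full(10, 5.0))
        assert set(qa.labels) == {"Q1"}
        assert any("degenerate" in r.message for r in caplog.records)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            assign_quartiles([1, 2, 3])

    def test_continuous_values_split_near_evenly(self, rng):
        """With distinct (continuous) values the empirical quartiles hold
        25 +/- 5% each; integer-valued indices can deviate through ties."""
        qa = assign_quartiles(rng.normal(size=251))
        for q in ("Q1", "Q2", "Q3", "Q4"):
            assert 0.20 <= len(qa.members(q)) / 251 <= 0.30

    def test_cohort_quartiles_partition_everyone(self, default_study):
        _, cohort = default_study
        qa = assign_quartiles(cohort.frame["index"].to_numpy(float))
        counts = {q: len(qa.members(q)) for q in ("Q1", "Q2", "Q3", "Q4")}
        assert sum(counts.values()) == len(cohort.frame)
        assert counts["Q1"] > 0

    def test_ties_never_straddle_bins(self, default_study):
        _, cohort = default_study
        vals = cohort.frame["index"].to_numpy(float)
        qa = assign_quartiles(vals)
        for v in np.unique(vals):
            assert len(set(qa.labels[vals == v])) == 1


class TestDistanceToNearest:
    def test_three_four_five_triangle(self):
        d = distance_to_nearest([(0.0, 0.0)], layer([(3.0, 4.0), (10.0, 0.0)]))
        assert d[0] == 5.0

    def test_coincident_point(self):
        assert distance_to_nearest([(2.0, 2.0)], layer([(2.0, 2.0)]))[0] == 0.0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 1000, (50, 2))
        fac = rng.uniform(0, 1000, (10, 2))
        got = distance_to_nearest(pts, layer(fac))
        expected = np.min(
            np.sqrt(
                (pts[:, None, 0] - fac[None, :, 0]) ** 2
                + (pts[:, None, 1] - fac[None, :, 1]) ** 2
            ),
            axis=1,
        )
        np.testing.assert_array_equal(got, expected)
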