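import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr
from shapely.geometry import LineString

from ensdm.grid import GridSpec, Raster
from ensdm.predictors import distance_raster
from ensdm.synth import (
    FutureScenario,
    LandscapeSpec,
    SamplingError,
    TruthModel,
    make_future,
    make_landscape,
    make_polygons,
    sample_occurrences,
    true_suitability,
)


class TestLandscapeSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_rows": -1},
            {"n_rows": 5, "n_cols": 5},  # < 100 cells
            {"cell_size_km": 0},
            {"landcover_classes": 2},
            {"n_climate_layers": 3},
            {"autocorrelation_range_cells": 0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LandscapeSpec(**kwargs)


class TestMakeLandscape:
    def test_same_seed_bit_identical(self, small_spec, small_stack):
        again = make_landscape(small_spec)
        for name in small_stack.names:
            np.testing.assert_array_equal(again[name], small_stack[name])

    def test_different_seed_differs(self, small_spec, small_stack):
        other = make_landscape(LandscapeSpec(seed=small_spec.seed + 1, n_rows=60, n_cols=60))
        assert not np.array_equal(other["bio15"], small_stack["bio15"])

    def test_expected_layers_aligned_and_bounded(self, small_stack):
        expected = {
            "bio18", "bio19", "bio15", "bio2", "bio3", "elevation", "slope",
            "landcover", "human_footprint", "human_modification",
            "dist_river", "dist_road", "ndvi", "tree_canopy", "forest_type",
        }
        assert expected <= set(small_stack.names)
        for name in ("human_footprint", "human_modification", "ndvi"):
            v = small_stack[name]
            assert v.min() >= 0.0 and v.max() <= 1.0
        assert (small_stack["slope"] >= 0).all()
        assert "landcover" in small_stack.categorical

    def test_no_rivers_gives_degenerate_sentinel_distance(self):
        spec = LandscapeSpec(seed=3, n_rows=20, n_cols=20, river_count=0)
        st = make_landscape(spec)
        assert "dist_river" in st.meta["degenerate_layers"]
        assert np.unique(st["dist_river"]).size == 1  # uniform sentinel

    def test_human_layers_track_anthropogenic_landcover(self, small_stack):
        anthro = small_stack["landcover"] == 0
        hfp = small_stack["human_footprint"]
        assert hfp[anthro].mean() > hfp[~anthro].mean()


class TestSlopeAndDistance:
    def test_flat_elevation_gives_zero_slope(self):
        # slope is a derivative: constant elevation => identically zero
        z = np.full((10, 10), 500.0)
        dzdy, dzdx = np.gradient(z, 1000.0)
        slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        assert (slope == 0).all()

    def test_distance_zero_on_line_and_linear_offset(self):
        g = GridSpec(n_rows=5, n_cols=5, cell_size_km=1.0)
        # vertical line through the center of column 2
        line = LineString([(2.5, 0), (2.5, 5)])
        r = distance_raster([line], g)
        np.testing.assert_allclose(r.values[:, 2], 0.0, atol=1e-12)
        for col in range(5):
            np.testing.assert_allclose(r.values[:, col], abs(col - 2) * 1.0)

    def test_distance_against_bruteforce_segments(self, rng):
        g = GridSpec(n_rows=8, n_cols=8, cell_size_km=1.0)
        lines = [
            LineString(rng.uniform(0, 8, size=(3, 2))),
            LineString(rng.uniform(0, 8, size=(2, 2))),
        ]
        r = distance_raster(lines, g)
        xs, ys = g.cell_centers()
        from shapely.geometry import Point

        for i in range(8):
            for j in range(8):
                d = min(ln.distance(Point(xs[i, j], ys[i, j])) for ln in lines)
                assert r.values[i, j] == pytest.approx(d, abs=1e-9)

    def test_distance_nondecreasing_with_chebyshev_rings(self):
        g = GridSpec(n_rows=9, n_cols=9, cell_size_km=1.0)
        line = LineString([(4.5, 4.4), (4.5, 4.6)])  # point-like feature at center
        r = distance_raster([line], g)
        ring = np.maximum(np.abs(np.arange(9) - 4)[:, None], np.abs(np.arange(9) - 4)[None, :])
        means = [r.values[ring == k].min() for k in range(5)]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestTrueSuitability:
    def test_zero_model_gives_uniform_half(self, small_stack):
        t = TruthModel(active_predictors=("bio18",), coefficients=(0.0,), intercept=0.0)
        suit = true_suitability(small_stack, t)
        np.testing.assert_allclose(suit.values, 0.5)

    def test_large_negative_intercept_drives_to_zero(self, small_stack):
        lo = true_suitability(
            small_stack, TruthModel(("bio18",), (1.0,), intercept=-10.0)
        )
        lower = true_suitability(
            small_stack, TruthModel(("bio18",), (1.0,), intercept=-20.0)
        )
        assert lo.values.max() < 0.05
        assert (lower.values <= lo.values + 1e-15).all()

    def test_single_predictor_monotone(self, small_stack):
        t = TruthModel(active_predictors=("bio18",), coefficients=(1.0,), intercept=0.0)
        suit = true_suitability(small_stack, t)
        order = np.argsort(small_stack["bio18"].ravel())
        s = suit.values.ravel()[order]
        assert (np.diff(s) >= -1e-15).all()

    def test_missing_layer_raises(self, small_stack):
        with pytest.raises(KeyError):
            true_suitability(small_stack, TruthModel(("nope",), (1.0,)))


class TestSampleOccurrences:
    def test_point_mass_sampled(self, flat_grid):
        vals = np.zeros(flat_grid.shape)
        vals[3, 7] = 1.0
        occ = sample_occurrences(Raster(vals, flat_grid), n=1, seed=0)
        x, y = flat_grid.xy(np.array([3]), np.array([7]))
        assert occ.xy[0, 0] == x[0] and occ.xy[0, 1] == y[0]

    def test_seed_reproducible(self, small_suitability):
        a = sample_occurrences(small_suitability, 50, seed=4)
        b = sample_occurrences(small_suitability, 50, seed=4)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_oversampling_raises(self, flat_grid):
        vals = np.zeros(flat_grid.shape)
        vals[0, 0] = 1.0
        with pytest.raises(SamplingError):
            sample_occurrences(Raster(vals, flat_grid), n=2, seed=0)

    def test_uniform_suitability_draws_uniformly(self, flat_grid):
        # with-replacement across repeated unit draws: multinomial uniformity
        vals = np.ones(flat_grid.shape)
        counts = np.zeros(flat_grid.n_cells)
        rng = np.random.default_rng(0)
        for k in range(400):
            occ = sample_occurrences(Raster(vals, flat_grid), n=10, seed=int(rng.integers(2**31)))
            row, col = flat_grid.rowcol(occ.xy[:, 0], occ.xy[:, 1])
            np.add.at(counts, row * flat_grid.n_cols + col, 1)
        p = chisquare(counts).pvalue
        assert p > 1e-4

    def test_draw_frequency_tracks_suitability(self, small_suitability):
        # proportional sampling: per-cell frequency correlates with suitability
        counts = np.zeros(small_suitability.grid.n_cells)
        rng = np.random.default_rng(1)
        for _ in range(150):
            occ = sample_occurrences(small_suitability, 60, seed=int(rng.integers(2**31)))
            row, col = small_suitability.grid.rowcol(occ.xy[:, 0], occ.xy[:, 1])
            np.add.at(counts, row * small_suitability.grid.n_cols + col, 1)
        rho = spearmanr(counts, small_suitability.values.ravel()).statistic
        assert rho > 0.7


class TestMakeFuture:
    def test_zero_deltas_identity(self, small_stack):
        fut = make_future(small_stack, FutureScenario(name="s"), seed=0)
        for name in small_stack.names:
            np.testing.assert_array_equal(fut[name], small_stack[name])

    def test_offset_applied_exactly(self, small_stack):
        fut = make_future(small_stack, FutureScenario(offsets={"bio18": 2.0}), seed=0)
        np.testing.assert_allclose(fut["bio18"] - small_stack["bio18"], 2.0)

    def test_missing_layer_delta_raises(self, small_stack):
        with pytest.raises(KeyError):
            make_future(small_stack, FutureScenario(offsets={"nope": 1.0}))

    def test_conversion_fraction_of_natural_cells(self, small_stack):
        frac = 0.1
        fut = make_future(
            small_stack, FutureScenario(landcover_conversion=frac), seed=5
        )
        nat_before = small_stack["landcover"] != 0
        changed = (fut["landcover"] != small_stack["landcover"]).sum()
        assert changed == pytest.approx(frac * nat_before.sum(), rel=0.02)
        # conversion only ever natural -> anthropogenic
        assert ((fut["landcover"] == 0) | nat_before).all()

    def test_human_layers_constant(self, small_stack):
        fut = make_future(
            small_stack,
            FutureScenario(offsets={"bio18": 5.0}, landcover_conversion=0.2),
            seed=2,
        )
        np.testing.assert_array_equal(fut["human_footprint"], small_stack["human_footprint"])
        np.testing.assert_array_equal(
            fut["human_modification"], small_stack["human_modification"]
        )


class TestMakePolygons:
    @pytest.mark.parametrize("kind", ["protected_area", "zone", "range_category"])
    def test_within_extent_nonoverlapping_deterministic(self, small_spec, kind):
        polys = make_polygons(small_spec, kind, seed=9)
        again = make_polygons(small_spec, kind, seed=9)
        extent = small_spec.grid().extent_km
        from shapely.geometry import box as sbox

        frame = sbox(*[extent[i] for i in (0, 1, 2, 3)])
        for (g1, _), (g2, _) in zip(polys, again):
            assert g1.equals(g2)
            assert frame.buffer(1e-9).contains(g1)
        geoms = polys.geometries
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert geoms[i].intersection(geoms[j]).area < 1e-9

    def test_range_categories_labelled(self, small_spec):
        polys = make_polygons(small_spec, "range_category", seed=0)
        labels = {p["label"] for p in polys.properties}
        assert labels == {"extant", "uncertain", "extinct"}

    def test_unknown_kind_raises(self, small_spec):
        with pytest.raises(ValueError):
            make_polygons(small_spec, "nope")
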