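import itertools

import numpy as np
import pytest
from shapely.geometry import box

from ensdm.grid import GridSpec, Raster
from ensdm.habitat import (
    ConfigurationError,
    PriorityMap,
    SuitabilityClassMap,
    apply_mask,
    area_report,
    class_percentages,
    disturbance_mask,
    range_shift,
    rank_priorities,
    reclassify,
    round_half_up,
)
from ensdm.synth import PolygonSet


def surf(vals, g=None):
    vals = np.asarray(vals, float)
    g = g or GridSpec(n_rows=vals.shape[0], n_cols=vals.shape[1])
    return Raster(vals, g)


def cmap(codes, g=None, model="m", scenario="current"):
    codes = np.asarray(codes, int)
    g = g or GridSpec(n_rows=codes.shape[0], n_cols=codes.shape[1])
    return SuitabilityClassMap(codes, g, np.ones(codes.shape, bool), model, scenario)


class TestReclassify:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0), (0.19, 0), (0.2, 1), (0.39, 1), (0.4, 2), (0.45, 2), (0.6, 3), (1.0, 3)],
    )
    def test_threshold_boundaries_half_open(self, value, expected):
        cm = reclassify(surf(np.full((2, 2), value)))
        assert (cm.codes == expected).all()

    def test_all_zero_surface_all_unsuitable(self):
        assert (reclassify(surf(np.zeros((3, 3)))).codes == 0).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            reclassify(surf(np.full((2, 2), 1.5)))

    def test_monotone_in_suitability(self, rng):
        a = rng.uniform(size=(6, 6))
        b = np.clip(a + rng.uniform(0, 0.3, size=(6, 6)), 0, 1)
        ca, cb = reclassify(surf(a)), reclassify(surf(b))
        assert (cb.codes >= ca.codes).all()

    def test_nodata_propagates(self):
        g = GridSpec(n_rows=2, n_cols=2)
        mask = np.array([[True, False], [True, True]])
        cm = reclassify(Raster(np.full((2, 2), 0.5), g, mask))
        assert not cm.mask[0, 1]


class TestDisturbance:
    def test_zero_pressure_all_low(self):
        m = disturbance_mask(surf(np.zeros((3, 3))), surf(np.zeros((3, 3))))
        assert (m.values == 0).all()

    def test_saturated_cell_high(self):
        m = disturbance_mask(surf(np.ones((2, 2))), surf(np.ones((2, 2))))
        assert (m.values == 1).all()

    def test_mean_rule_below_threshold(self):
        # hfp 0.2, hmod 0.3 -> ensemble 0.25 -> low disturbance
        m = disturbance_mask(surf(np.full((2, 2), 0.2)), surf(np.full((2, 2), 0.3)))
        assert (m.values == 0).all()

    def test_mean_rule_above_threshold(self):
        m = disturbance_mask(surf(np.full((2, 2), 0.5)), surf(np.full((2, 2), 0.2)))
        assert (m.values == 1).all()

    def test_out_of_unit_layers_are_normalized(self):
        # footprint on a 0-50 scale: min-max brings it back to [0,1]
        vals = np.array([[0.0, 50.0], [25.0, 10.0]])
        m = disturbance_mask(surf(vals), surf(vals / 50.0))
        assert m.values[0, 1] == 1 and m.values[0, 0] == 0

    def test_misaligned_raises(self):
        from ensdm.grid import AlignmentError

        with pytest.raises(AlignmentError):
            disturbance_mask(surf(np.zeros((2, 2))), surf(np.zeros((3, 3))))


class TestApplyMask:
    def test_all_high_mask_clears_everything(self):
        cm = cmap(np.full((3, 3), 3))
        out = apply_mask(cm, surf(np.ones((3, 3))))
        assert (out.codes == 0).all()

    def test_all_low_mask_is_identity(self):
        cm = cmap(np.arange(9).reshape(3, 3) % 4)
        out = apply_mask(cm, surf(np.zeros((3, 3))))
        np.testing.assert_array_equal(out.codes, cm.codes)

    def test_checkerboard_per_cell_oracle(self, rng):
        codes = rng.integers(0, 4, size=(6, 6))
        mask = np.indices((6, 6)).sum(0) % 2
        out = apply_mask(cmap(codes), surf(mask))
        for i, j in itertools.product(range(6), range(6)):
            expected = 0 if mask[i, j] else codes[i, j]
            assert out.codes[i, j] == expected


class TestAreaAccounting:
    def test_round_half_up_convention(self):
        assert round_half_up(1.325) == 1.33
        assert round_half_up(1.314999) == 1.31

    def test_suitable_percent_uses_rounded_components(self):
        # medium 15133.31 and high 3605.13 of 273490.36 km^2:
        # 5.53% + 1.32% = 6.85% suitable
        out = class_percentages(
            {0: 0.0, 1: 0.0, 2: 15133.31, 3: 3605.13}, 273490.36
        )
        assert out["percent"][2] == 5.53
        assert out["percent"][3] == 1.32
        assert out["suitable_percent"] == 6.85

    def test_high_class_share(self):
        out = class_percentages({3: 6170.28}, 273490.36)
        assert out["percent"][3] == 2.26

    def test_report_areas_sum_to_zone_area(self, rng):
        codes = rng.integers(0, 4, size=(10, 10))
        rep = area_report([cmap(codes)])
        per_class = rep[rep["class"] != "suitable"]
        assert per_class["area_km2"].sum() == pytest.approx(100.0, rel=1e-4)
        assert per_class["percent_raw"].sum() == pytest.approx(100.0, rel=1e-4)

    def test_single_cell_zone_percent_degenerate(self):
        codes = np.zeros((4, 4), int)
        codes[0, 0] = 3
        zones = PolygonSet(
            "zone", [box(0.0, 3.0, 1.0, 4.0)], [{"id": "z"}]  # exactly cell (0,0)
        )
        rep = area_report([cmap(codes)], zones=zones)
        highs = rep[(rep["class"] == "high")]["percent_of_zone"].iloc[0]
        assert highs == 100.0

    def test_empty_zone_gives_zero_rows_not_failure(self):
        zones = PolygonSet("zone", [box(100, 100, 101, 101)], [{"id": "far"}])
        rep = area_report([cmap(np.zeros((4, 4), int))], zones=zones)
        assert (rep["area_km2"] == 0).all()

    def test_total_area_override_reproduces_table_arithmetic(self):
        # one high cell of a 2x2 grid but percent taken of a stated total
        codes = np.array([[3, 0], [0, 0]])
        rep = area_report([cmap(codes)], total_area_km2=50.0)
        row = rep[rep["class"] == "high"].iloc[0]
        assert row["percent_of_zone"] == 2.0


def _dist(vals):
    return surf(np.asarray(vals, float))


class TestRankPriorities:
    def _maps(self, h, ln, cn, lf, cf, dist):
        g = GridSpec(n_rows=1, n_cols=1)
        mk = lambda v, scen="current": SuitabilityClassMap(
            np.array([[v]]), g, np.ones((1, 1), bool), "m", scen
        )
        return rank_priorities(
            mk(h), mk(ln), mk(cn),
            [mk(lf, "rcp45"), mk(lf, "rcp85")],
            [mk(cf, "rcp45"), mk(cf, "rcp85")],
            Raster(np.array([[dist]]), g),
        )

    def test_high_everywhere_low_disturbance_is_very_high(self):
        pm = self._maps(3, 3, 3, 3, 3, 0)
        assert pm.codes[0, 0] == 3

    def test_high_in_disturbed_cell_is_none(self):
        pm = self._maps(3, 3, 3, 3, 3, 1)
        assert pm.codes[0, 0] == 0

    def test_medium_current_unsuitable_future_is_high_not_possible(self):
        pm = self._maps(2, 2, 2, 0, 2, 0)
        assert pm.codes[0, 0] == 2

    def test_rule_table_exhaustive_enumeration(self):
        # brute-force the decision table over every class/disturbance combo
        for h, ln, cn, lf, cf, d in itertools.product(
            range(4), range(4), range(4), range(4), range(4), (0, 1)
        ):
            pm = self._maps(h, ln, cn, lf, cf, d)
            agree = ln >= 2 and cn >= 2
            if d == 1:
                expected = 0
            elif h == 3 and agree:
                expected = 3
            elif h == 2 and agree:
                expected = 2
            elif lf >= 2 and cf >= 2:
                expected = 1
            else:
                expected = 0
            assert pm.codes[0, 0] == expected, (h, ln, cn, lf, cf, d)

    def test_missing_scenario_rejected(self):
        g = GridSpec(n_rows=1, n_cols=1)
        mk = lambda scen="current": SuitabilityClassMap(
            np.array([[3]]), g, np.ones((1, 1), bool), "m", scen
        )
        with pytest.raises(ConfigurationError):
            rank_priorities(
                mk(), mk(), mk(), [mk("rcp45")], [mk("rcp45")], Raster(np.zeros((1, 1)), g)
            )

    def test_categories_mutually_exclusive_and_exhaustive(self, rng):
        g = GridSpec(n_rows=8, n_cols=8)
        mk = lambda scen="current": SuitabilityClassMap(
            rng.integers(0, 4, size=(8, 8)), g, np.ones((8, 8), bool), "m", scen
        )
        dist = Raster(rng.integers(0, 2, size=(8, 8)).astype(float), g)
        pm = rank_priorities(
            mk(), mk(), mk(), [mk("rcp45"), mk("rcp85")], [mk("rcp45"), mk("rcp85")], dist
        )
        assert sum(pm.counts().values()) == 64


class TestRangeShift:
    def test_identical_maps_no_change(self):
        cm = cmap(np.array([[2, 0], [0, 3]]))
        rs = range_shift(cm, cm)
        assert rs["gain_km2"] == rs["loss_km2"] == 0
        assert rs["centroid_shift_km"] == (0.0, 0.0)

    def test_northward_translation_exact_vector(self):
        codes0 = np.zeros((6, 6), int)
        codes0[4, 2] = 3  # suitable block in the south
        codes1 = np.zeros((6, 6), int)
        codes1[1, 2] = 3  # moved 3 cells north
        rs = range_shift(cmap(codes0), cmap(codes1))
        assert rs["centroid_shift_km"] == (0.0, 3.0)
        assert rs["stable_km2"] == 0 and rs["gain_km2"] == 1 and rs["loss_km2"] == 1

    def test_random_pair_matches_counting_oracle(self, rng):
        a = rng.integers(0, 4, size=(7, 7))
        b = rng.integers(0, 4, size=(7, 7))
        rs = range_shift(cmap(a), cmap(b))
        sa, sb = a >= 2, b >= 2
        assert rs["gain_km2"] == (sb & ~sa).sum()
        assert rs["loss_km2"] == (sa & ~sb).sum()
        assert rs["stable_km2"] == (sa & sb).sum()
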