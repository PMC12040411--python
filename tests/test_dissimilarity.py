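"""Separation measures: distances, indices, interquartile means, quartiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import ecodist as ed
from ecodist import harmonics as har
from ecodist.dissimilarity import KM_PER_DEGREE


class TestGeoDistance:
    def test_identical_points_zero(self):
        assert ed.geo_distance((40.0, -110.0), (40.0, -110.0)) == 0.0

    def test_one_degree_latitude_is_111_195_km(self):
        assert ed.geo_distance((0.0, 0.0), (1.0, 0.0)) == pytest.approx(
            111.195, abs=1e-3
        )

    def test_longitude_shrinks_with_cosine_of_latitude(self):
        d = ed.geo_distance((60.0, 0.0), (60.0, 1.0))
        assert d == pytest.approx(111.195 * math.cos(math.radians(60)), abs=1e-3)
        assert d == pytest.approx(55.597, abs=1e-3)

    def test_degrees_euclidean_mode_ignores_latitude(self):
        d = ed.geo_distance((60.0, 0.0), (60.0, 1.0), mode="degrees-euclidean")
        assert d == pytest.approx(KM_PER_DEGREE, abs=1e-9)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            ed.geo_distance((95.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError, match="longitude"):
            ed.geo_distance((0.0, 200.0), (0.0, 0.0))

    @given(
        pts=st.lists(
            st.tuples(
                st.floats(min_value=30, max_value=50),
                st.floats(min_value=-125, max_value=-100),
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality_over_study_area(self, pts):
        a, b, c = pts
        # degrees-euclidean is a true planar metric; the equirectangular
        # variant uses a per-pair mean-latitude cosine and can undershoot by
        # a fraction of a percent, so it gets a small relative slack
        d_lit = [
            ed.geo_distance(x, y, mode="degrees-euclidean")
            for x, y in ((a, c), (a, b), (b, c))
        ]
        assert d_lit[0] <= d_lit[1] + d_lit[2] + 1e-9
        d_eq = [ed.geo_distance(x, y) for x, y in ((a, c), (a, b), (b, c))]
        assert d_eq[0] <= (d_eq[1] + d_eq[2]) * 1.01 + 1e-9


class TestIndicatorCentroids:
    def _plots(self, values_by_eco, indicators=("i1", "i2")):
        rows = []
        for eco, vals in values_by_eco.items():
            for v in vals:
                rows.append({"ecoregion_id": eco, **dict(zip(indicators, v))})
        return pd.DataFrame(rows)

    def test_mirror_image_ecoregions_have_opposite_centroids(self):
        plots = self._plots(
            {"A": [(10, 20), (30, 40)], "B": [(90, 80), (70, 60)]}
        )
        cen = ed.indicator_centroids(plots, ["i1", "i2"], min_plots=2)
        a = cen.loc["A", ["i1", "i2"]].to_numpy(float)
        b = cen.loc["B", ["i1", "i2"]].to_numpy(float)
        assert np.allclose(a, -b)

    def test_zero_variance_indicator_dropped_with_warning(self, caplog):
        plots = self._plots(
            {"A": [(10, 5), (30, 5)], "B": [(90, 5), (70, 5)]}
        )
        with caplog.at_level("WARNING"):
            cen = ed.indicator_centroids(plots, ["i1", "i2"], min_plots=2)
        assert list(cen.columns) == ["i1", "n_plots"]
        assert "i2" in caplog.text

    def test_ecoregion_below_threshold_excluded(self):
        plots = self._plots(
            {"A": [(1, 2), (3, 4)], "B": [(5, 6), (7, 8)], "C": [(9, 9)]}
        )
        cen = ed.indicator_centroids(plots, ["i1", "i2"], min_plots=2)
        assert sorted(cen.index) == ["A", "B"]

    def test_fewer_than_two_qualifying_rejected(self):
        plots = self._plots({"A": [(1, 2), (3, 4)], "B": [(5, 6)]})
        with pytest.raises(ValueError, match=">= 2 ecoregions"):
            ed.indicator_centroids(plots, ["i1", "i2"], min_plots=2)


class TestEcoDisIS:
    def test_identical_centroids_zero(self):
        assert ed.eco_dis_is(np.ones(20), np.ones(20)) == 0.0

    def test_unit_difference_in_one_dimension(self):
        a = np.zeros(20)
        b = np.zeros(20)
        b[7] = 1.0
        assert ed.eco_dis_is(a, b) == 1.0

    def test_small_difference_in_all_dimensions(self):
        a = np.zeros(20)
        b = np.full(20, 0.1)
        assert ed.eco_dis_is(a, b) == pytest.approx(math.sqrt(20 * 0.01), abs=1e-9)
        assert ed.eco_dis_is(a, b) == pytest.approx(0.44721, abs=1e-5)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="arity"):
            ed.eco_dis_is(np.zeros(20), np.zeros(19))


def _descriptor(amp, phase, scaled=True, eco="E"):
    amp = np.atleast_2d(np.asarray(amp, float))
    phase = np.atleast_2d(np.asarray(phase, float))
    return har.HarmonicDescriptor(
        ecoregion_id=eco,
        variables=[f"v{i}" for i in range(amp.shape[0])],
        amplitude=amp,
        phase=phase,
        scaled=scaled,
    )


class TestDeltaAmplitudePhase:
    def test_identical_descriptors_zero(self):
        d = _descriptor(np.full((6, 2), 0.4), np.zeros((6, 2)))
        assert ed.delta_amplitude(d, d) == 0.0
        assert ed.delta_phase(d, d) == 0.0

    def test_full_amplitude_contrast_is_one(self):
        d1 = _descriptor(np.ones((6, 2)), np.zeros((6, 2)))
        d0 = _descriptor(np.zeros((6, 2)), np.zeros((6, 2)))
        assert ed.delta_amplitude(d1, d0) == 1.0

    def test_mean_of_absolute_differences(self):
        d1 = _descriptor([[0.8], [0.9]], [[0.0], [0.0]])
        d2 = _descriptor([[0.6], [0.3]], [[0.0], [0.0]])
        assert ed.delta_amplitude(d1, d2) == pytest.approx(0.4, abs=1e-12)

    def test_unscaled_descriptors_rejected(self):
        d = _descriptor([[0.5]], [[0.0]], scaled=False)
        with pytest.raises(ValueError, match="scaled"):
            ed.delta_amplitude(d, d)

    def test_antiphase_normalizes_to_one(self):
        d1 = _descriptor(np.ones((3, 2)), np.full((3, 2), np.pi / 2))
        d2 = _descriptor(np.ones((3, 2)), np.full((3, 2), -np.pi / 2))
        assert ed.delta_phase(d1, d2) == pytest.approx(1.0, abs=1e-12)

    def test_circular_difference_mean(self):
        # I=1, J=2 with circular differences pi/2 and pi -> mean 3*pi/4 -> 0.75
        d1 = _descriptor([[0.0, 0.0]], [[0.0, 0.0]])
        d2 = _descriptor([[0.0, 0.0]], [[np.pi / 2, np.pi]])
        assert ed.delta_phase(d1, d2) == pytest.approx(0.75, abs=1e-12)

    def test_wraparound_uses_shorter_arc(self):
        d1 = _descriptor([[0.0]], [[3.0]])
        d2 = _descriptor([[0.0]], [[-3.0]])
        expected = (2 * np.pi - 6.0) / np.pi
        assert ed.delta_phase(d1, d2) == pytest.approx(expected, abs=1e-12)


class TestEcoDisRS:
    def test_self_comparison_is_exactly_one(self):
        assert ed.eco_dis_rs(0.0, 0.0) == 1.0

    def test_maximum_corner_matches_printed_bound(self):
        assert ed.eco_dis_rs(1.0, 1.0) == pytest.approx(2 * (2 - math.cos(1.0)))
        assert round(ed.eco_dis_rs(1.0, 1.0), 3) == 2.919

    def test_midpoint_value(self):
        assert ed.eco_dis_rs(0.5, 0.5) == pytest.approx(
            1.5 * (2 - math.cos(0.5)), abs=1e-12
        )
        assert ed.eco_dis_rs(0.5, 0.5) == pytest.approx(1.68363, abs=1e-5)

    def test_out_of_range_and_non_finite_rejected(self):
        for bad in ((1.2, 0.5), (-0.1, 0.5), (0.5, 1.2), (0.5, -0.1)):
            with pytest.raises(ValueError):
                ed.eco_dis_rs(*bad)
        with pytest.raises(ValueError, match="finite"):
            ed.eco_dis_rs(float("nan"), 0.5)

    def test_matches_direct_formula_on_random_grid(self, rng):
        da = rng.uniform(0, 1, 10_000)
        dp = rng.uniform(0, 1, 10_000)
        expected = (1 + da) * (np.sin(dp - np.pi / 2) + 2)
        got = ed.eco_dis_rs(da, dp)
        assert np.max(np.abs(got - expected)) <= 1e-12

    def test_strictly_increasing_in_both_arguments(self):
        grid = np.linspace(0, 1, 101)
        along_a = ed.eco_dis_rs(grid, np.full_like(grid, 0.3))
        along_p = ed.eco_dis_rs(np.full_like(grid, 0.3), grid)
        assert np.all(np.diff(along_a) > 0)
        assert np.all(np.diff(along_p) > 0)


class TestPairwiseTable:
    def test_small_table_counts_symmetry_and_no_self_pairs(self, small_pairwise):
        table = small_pairwise
        assert len(table) == 8 * 7
        assert not (table["eco_m"] == table["eco_n"]).any()
        rev = table.set_index(["eco_n", "eco_m"])
        fwd = table.set_index(["eco_m", "eco_n"])
        for col in ("geoDist", "ecoDisIS", "deltaA", "deltaP", "ecoDisRS"):
            assert np.allclose(fwd[col], rev[col].reindex(fwd.index))

    def test_value_ranges(self, small_pairwise):
        t = small_pairwise
        assert (t["geoDist"] >= 0).all()
        assert (t["ecoDisIS"] >= 0).all()
        assert t["deltaA"].between(0, 1).all()
        assert t["deltaP"].between(0, 1).all()
        assert t["ecoDisRS"].between(1, 2 * (2 - math.cos(1.0))).all()

    def test_ecodis_triangle_inequality_on_random_triples(self, small_pairwise, rng):
        t = small_pairwise.set_index(["eco_m", "eco_n"])["ecoDisIS"]
        ids = sorted({i for i, _ in t.index})
        for _ in range(50):
            a, b, c = rng.choice(ids, 3, replace=False)
            assert t[(a, c)] <= t[(a, b)] + t[(b, c)] + 1e-9

    def test_is_and_rs_positively_rank_correlated(self, small_pairwise):
        rho = stats.spearmanr(
            small_pairwise["ecoDisIS"], small_pairwise["ecoDisRS"]
        ).statistic
        assert rho > 0

    def test_id_mismatch_across_inputs_rejected(self, small_collection):
        c = small_collection
        scaled = ed.scale_amplitudes(ed.descriptor_sets(c.series))
        centroids = ed.indicator_centroids(c.plots, c.indicator_names, min_plots=30)
        geo = c.plots.groupby("ecoregion_id")[["lat", "lon"]].mean().reset_index()
        with pytest.raises(ValueError, match="do not match"):
            ed.pairwise_table(centroids, scaled[:-1], geo)


class TestInterquartileMean:
    def test_first_eight_integers(self):
        assert ed.interquartile_mean(range(1, 9)) == 1.5

    def test_all_equal_and_singleton(self):
        assert ed.interquartile_mean([3.3] * 10) == pytest.approx(3.3)
        assert ed.interquartile_mean([7.0]) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ed.interquartile_mean([])

    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_sort_and_slice_oracle(self, values):
        k = math.ceil(0.25 * len(values))
        oracle = float(np.mean(sorted(values)[:k]))
        assert ed.interquartile_mean(values) == pytest.approx(oracle, rel=1e-12)

    def test_tie_break_by_id_is_deterministic(self):
        values = [2.0, 1.0, 1.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        ids = ["h", "z", "a", "d", "e", "f", "g", "b"]
        # k = 2: the two smallest are the tied 1.0s regardless of id order
        assert ed.interquartile_mean(values, ids=ids) == 1.0


class TestEcoDisInt:
    def _pairwise(self, target, values):
        rows = []
        for i, v in enumerate(values):
            rows.append(
                {"eco_m": target, "eco_n": f"R{i:02d}", "ecoDisRS": v,
                 "ecoDisIS": v * 2}
            )
        return pd.DataFrame(rows)

    def test_k_equals_one_for_four_references(self):
        pw = self._pairwise("T", [4.0, 3.0, 2.0, 1.0])
        rec = ed.eco_dis_int(pw, "T", [f"R{i:02d}" for i in range(4)])
        assert rec["value"] == 1.0
        assert rec["k"] == 1

    def test_seventy_references_average_eighteen_smallest(self, rng):
        values = rng.uniform(1, 3, 70)
        pw = self._pairwise("T", values)
        rec = ed.eco_dis_int(pw, "T", [f"R{i:02d}" for i in range(70)])
        assert rec["k"] == 18
        assert rec["value"] == pytest.approx(np.mean(np.sort(values)[:18]))

    def test_constant_references_return_constant(self):
        pw = self._pairwise("T", [2.5] * 10)
        rec = ed.eco_dis_int(pw, "T", [f"R{i:02d}" for i in range(10)])
        assert rec["value"] == pytest.approx(2.5)

    def test_target_excluded_and_empty_reference_rejected(self):
        pw = self._pairwise("T", [1.0, 2.0])
        rec = ed.eco_dis_int(pw, "T", ["T", "R00", "R01"])
        assert rec["reference_set_size"] == 2
        with pytest.raises(ValueError, match="empty"):
            ed.eco_dis_int(pw, "T", ["T"])

    def test_bulk_table_carries_both_measures(self, small_pairwise):
        ids = sorted(set(small_pairwise["eco_m"]))
        bulk = ed.bulk_table(small_pairwise, reference_ids=ids)
        assert len(bulk) == len(ids)
        assert (bulk["ecoDisINT_RS"] >= 1.0).all()
        assert set(bulk["quartile"]) <= {"Q1", "Q2", "Q3", "Q4"}


class TestQuartileAssign:
    def test_one_to_eight_boundaries_and_labels(self):
        bounds, labels = ed.quartile_assign(np.arange(1, 9, dtype=float))
        assert (bounds["q25"], bounds["q50"], bounds["q75"]) == (2.75, 4.5, 6.25)
        assert list(labels) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]

    def test_four_distinct_values_one_per_quartile(self):
        _, labels = ed.quartile_assign([10.0, 20.0, 30.0, 40.0])
        assert list(labels) == ["Q1", "Q2", "Q3", "Q4"]

    def test_value_on_cut_point_goes_to_upper_bin(self):
        # cut points of [0,2,4,6,8] are exactly 2, 4, 6; right-open bins send
        # each boundary value upward
        _, labels = ed.quartile_assign([0.0, 2.0, 4.0, 6.0, 8.0])
        assert list(labels) == ["Q1", "Q2", "Q3", "Q4", "Q4"]

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            ed.quartile_assign([1.0, 2.0, 3.0])

    @given(
        values=st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=60,
        )
    )
    def test_every_value_labelled_and_labels_monotone_in_value(self, values):
        _, labels = ed.quartile_assign(values)
        order = {"Q1": 1, "Q2": 2, "Q3": 3, "Q4": 4}
        ranks = np.array([order[l] for l in labels])
        v = np.asarray(values)
        idx = np.argsort(v, kind="stable")
        assert np.all(np.diff(ranks[idx]) >= 0)
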