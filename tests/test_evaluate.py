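"""Comparison statistics between predicted and experimental fluxes."""

import math

import numpy as np
import pandas as pd
import pytest

import cbfba as cb
from cbfba.evaluate import (ExperimentalFluxes, classify_active,
                            categorize_ranges, confusion_metrics,
                            detect_outliers, log_flux_correlation,
                            mean_difference_test, metabolic_adjustment,
                            range_overlap, read_experimental_fluxes,
                            subsystem_summary)


def make_experimental(rows, strain="s"):
    return ExperimentalFluxes(
        pd.DataFrame(rows, columns=["reaction_id", "mean", "ci_lower",
                                    "ci_upper"]), strain)


def make_samples(V, ids):
    return cb.SampleSet(np.asarray(V, dtype=float), list(ids), "cbfba", 0.0)


class TestClassifyActive:
    @pytest.mark.parametrize("flux,expected", [
        (1e-7, False), (0.0, False), (1e-6, True), (-2.0, True),
    ])
    def test_scalar(self, flux, expected):
        assert classify_active(flux) is expected

    def test_range_active_via_max(self):
        assert classify_active((0.0, 2e-6)) is True
        assert classify_active((0.0, 1e-8)) is False

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_active(1.0, threshold=0.0)


class TestConfusionMetrics:
    def test_perfect_agreement(self):
        out = confusion_metrics([True, False, True], [True, False, True])
        assert (out["sensitivity"], out["specificity"], out["accuracy"]) == \
            (1.0, 1.0, 1.0)

    def test_all_predicted_active(self):
        out = confusion_metrics([True] * 4, [True, True, False, False])
        assert out["sensitivity"] == 1.0
        assert out["specificity"] == 0.0

    def test_hand_counted_table(self):
        # TP=9, FN=1, TN=4, FP=6 -> 0.9 / 0.4 / 0.65
        pred = [True] * 9 + [False] * 1 + [False] * 4 + [True] * 6
        exp = [True] * 10 + [False] * 10
        out = confusion_metrics(pred, exp)
        assert out["sensitivity"] == pytest.approx(0.9)
        assert out["specificity"] == pytest.approx(0.4)
        assert out["accuracy"] == pytest.approx(0.65)

    def test_undefined_ratio_is_nan_not_zero(self):
        out = confusion_metrics([True, True], [True, True])
        assert math.isnan(out["specificity"])
        assert out["sensitivity"] == 1.0

    def test_counts_conserve_universe(self):
        rng = np.random.default_rng(0)
        pred, exp = rng.random(30) < 0.5, rng.random(30) < 0.5
        out = confusion_metrics(pred, exp)
        assert out["tp"] + out["tn"] + out["fp"] + out["fn"] == 30


class TestRangeOverlap:
    @pytest.mark.parametrize("pred,exp,expected", [
        ((0.0, 1.0), (0.5, 2.0), True),
        ((0.0, 1.0), (1.0, 2.0), True),    # closed intervals touch
        ((0.0, 1.0), (1.1, 2.0), False),
    ])
    def test_pairwise(self, pred, exp, expected):
        experimental = make_experimental(
            [("r", sum(exp) / 2, exp[0], exp[1])])
        out = range_overlap({"r": pred}, experimental)
        assert out["overlaps"]["r"] is expected

    def test_symmetric_in_intervals(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = np.sort(rng.random(2))
            b = np.sort(rng.random(2))
            ea = make_experimental([("r", a.mean(), a[0], a[1])])
            eb = make_experimental([("r", b.mean(), b[0], b[1])])
            assert range_overlap({"r": tuple(b)}, ea)["overlaps"]["r"] == \
                range_overlap({"r": tuple(a)}, eb)["overlaps"]["r"]

    def test_missing_interval_excluded_and_reported(self):
        experimental = make_experimental([("r", 0.5, 0.0, 1.0),
                                          ("q", 0.5, 0.0, 1.0)])
        out = range_overlap({"r": (0.0, 1.0)}, experimental)
        assert out["excluded"] == ["q"]
        assert out["fraction"] == 1.0


class TestCategorizeRanges:
    @pytest.mark.parametrize("pfba,cbfba,expected", [
        ((0.0, 5.0), (0.0, 3.0), "same_min_higher_max"),
        ((1.0, 5.0), (2.0, 3.0), "containment"),
        ((0.0, 3.0), (0.0, 3.0), "identical"),
        ((2.0, 5.0), (0.0, 3.0), "shifted_overlap"),
        ((4.0, 5.0), (0.0, 3.0), "shifted_disjoint"),
        ((0.0, 2.0), (0.0, 3.0), "other"),
    ])
    def test_examples(self, pfba, cbfba, expected):
        assert categorize_ranges(pfba, cbfba) == expected

    def test_exhaustive_and_exclusive(self):
        from cbfba.evaluate import RANGE_CATEGORIES
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = tuple(np.sort(rng.integers(0, 4, 2).astype(float)))
            c = tuple(np.sort(rng.integers(0, 4, 2).astype(float)))
            assert categorize_ranges(p, c) in RANGE_CATEGORIES


class TestLogFluxCorrelation:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 5.0, 9.0])
        assert log_flux_correlation(v, v) == pytest.approx(1.0)

    def test_power_law_is_log_linear(self):
        a = np.array([1.0, 3.0, 7.0, 20.0])
        assert log_flux_correlation(a, a ** 2.5) == pytest.approx(1.0)

    def test_four_point_closed_form(self):
        # log10 values (1,2,3,4) vs (1,3,2,5): r = 5.5 / sqrt(5 * 8.75)
        a = 10.0 ** np.array([1, 2, 3, 4])
        b = 10.0 ** np.array([1, 3, 2, 5])
        expected = 5.5 / math.sqrt(5.0 * 8.75)
        assert log_flux_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_too_few_points_gives_nan(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = log_flux_correlation([1.0, 2.0], [1.0, 2.0])
        assert math.isnan(out)

    def test_blocked_fluxes_never_enter_logs(self):
        a = np.array([0.0, 1.0, 2.0, 4.0])
        b = np.array([1.0, 0.0, 2.0, 4.0])
        with pytest.warns(UserWarning):
            out = log_flux_correlation(a, b)
        assert math.isnan(out)  # only 2 jointly active


class TestMeanDifferenceTest:
    def test_samples_equal_to_mean_no_difference(self):
        samples = make_samples(np.full((50, 1), 2.0), ["r"])
        experimental = make_experimental([("r", 2.0, 1.5, 2.5)])
        df = mean_difference_test(samples, experimental)
        assert bool(df.iloc[0].no_difference)
        assert bool(df.iloc[0].degenerate)

    def test_far_offset_is_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, size=(100, 1))
        samples = make_samples(x, ["r"])
        experimental = make_experimental([("r", 13.5, 13.0, 14.0)])
        df = mean_difference_test(samples, experimental)
        assert not bool(df.iloc[0].no_difference)

    def test_quantile_variant_agrees_on_obvious_cases(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.normal(0, 1, 200), rng.normal(9, 1, 200)])
        samples = make_samples(x, ["null", "shifted"])
        experimental = make_experimental([("null", 0.0, -1.0, 1.0),
                                          ("shifted", 0.0, -1.0, 1.0)])
        df = mean_difference_test(samples, experimental, test="quantile")
        out = df.set_index("reaction_id").no_difference
        assert bool(out["null"]) and not bool(out["shifted"])

    def test_fraction_reported(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, size=(100, 3))
        samples = make_samples(x, ["a", "b", "c"])
        experimental = make_experimental([("a", 0.0, -1, 1), ("b", 0.0, -1, 1),
                                          ("c", 50.0, 49, 51)])
        df = mean_difference_test(samples, experimental)
        assert 0.0 <= df.attrs["fraction_no_difference"] <= 1.0


class TestDetectOutliers:
    def test_collinear_points_no_outliers(self):
        x = 10.0 ** np.arange(1, 8)
        y = 10.0 ** (0.5 * np.arange(1, 8) + 1)
        out = detect_outliers(x, y)
        assert out["outliers"] == set()

    def test_displaced_point_flagged(self):
        lx = np.arange(1.0, 12.0)          # 11 points in log10 space
        ly = 2.0 * lx + 1.0
        base = detect_outliers(10.0 ** lx, 10.0 ** ly)
        ly[5] += 10.0 * max(base["s"], 1.0)  # displace far beyond scale
        out = detect_outliers(10.0 ** lx, 10.0 ** ly)
        assert out["outliers"] == {5}

    def test_matches_brute_force_residual_scan(self):
        rng = np.random.default_rng(4)
        lx = rng.normal(0, 1, 40)
        ly = 1.3 * lx + rng.normal(0, 0.4, 40)
        out = detect_outliers(10.0 ** lx, 10.0 ** ly)
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - slope * lx - intercept
        s = math.sqrt(np.sum(resid ** 2) / (len(lx) - 2))
        expected = {i for i in range(len(lx)) if abs(resid[i]) > 2 * s}
        assert out["outliers"] == expected

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            detect_outliers([1.0, 2.0], [1.0, 2.0])


class TestMetabolicAdjustment:
    def test_identical_constant_sets_zero_distance(self):
        V = np.tile([1.0, 2.0], (20, 1))
        a = make_samples(V, ["x", "y"])
        out = metabolic_adjustment(a, a, pairing_seed=0)
        np.testing.assert_allclose(out["distances"], 0.0, atol=1e-12)

    def test_constant_shift_closed_form(self):
        V = np.tile([1.0, 2.0, 3.0, 4.0], (30, 1))
        delta, k = 0.7, 3
        W = V.copy()
        W[:, :k] += delta
        out = metabolic_adjustment(make_samples(V, list("abcd")),
                                   make_samples(W, list("abcd")),
                                   pairing_seed=1)
        np.testing.assert_allclose(out["distances"],
                                   delta * math.sqrt(k), atol=1e-12)
        assert out["robust_mean"] == pytest.approx(delta * math.sqrt(k))

    def test_mismatched_universes_intersected_with_warning(self):
        a = make_samples(np.ones((5, 2)), ["x", "y"])
        b = make_samples(np.ones((5, 2)), ["y", "z"])
        with pytest.warns(UserWarning, match="intersection"):
            out = metabolic_adjustment(a, b, pairing_seed=0)
        assert out["reactions"] == ["y"]

    def test_distances_match_norm_recomputation(self):
        rng = np.random.default_rng(7)
        a = make_samples(rng.random((10, 3)), list("abc"))
        b = make_samples(rng.random((10, 3)), list("abc"))
        out = metabolic_adjustment(a, b, pairing_seed=3)
        assert out["n_pairs"] == 10
        assert np.all(out["distances"] >= 0)


class TestSubsystemSummary:
    def _model_with_subsystems(self):
        return cb.MetabolicModel(
            ["M"], ["r1", "r2", "r3"], np.array([[1.0, -1.0, 0.0]]),
            np.zeros(3), np.full(3, 10.0),
            subsystems={"r1": "glycolysis", "r2": "glycolysis"})

    def test_mean_log_range(self):
        model = self._model_with_subsystems()
        ranges = cb.FluxRanges(["r1", "r2"], np.array([0.0, 0.0]),
                               np.array([1.0, 10.0]), "pfba", 0.0)
        df = subsystem_summary({"pfba": ranges}, model)
        row = df[df.subsystem == "glycolysis"].iloc[0]
        assert row.mean_log10_range == pytest.approx(0.5)

    def test_unlabelled_reactions_omitted(self):
        model = self._model_with_subsystems()
        ranges = cb.FluxRanges(["r3"], np.array([0.0]), np.array([1.0]),
                               "pfba", 0.0)
        df = subsystem_summary({"pfba": ranges}, model)
        assert df.empty

    def test_matches_groupby_recomputation(self):
        rng = np.random.default_rng(9)
        ids = [f"r{i}" for i in range(12)]
        subs = {rid: ("A" if i < 7 else "B") for i, rid in enumerate(ids)}
        model = cb.MetabolicModel(
            ["M"], ids, rng.integers(-1, 2, (1, 12)).astype(float),
            np.zeros(12), np.full(12, 10.0), subsystems=subs)
        lo = np.zeros(12)
        hi = rng.random(12) + 0.1
        ranges = cb.FluxRanges(ids, lo, hi, "cbfba", 0.0)
        df = subsystem_summary({"cbfba": ranges}, model).set_index("subsystem")
        for name in ("A", "B"):
            member = [j for j, rid in enumerate(ids) if subs[rid] == name]
            expected = np.mean(np.log10(hi[member]))
            assert df.loc[name].mean_log10_range == pytest.approx(expected)


class TestExperimentalIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "exp.csv"
        path.write_text("reaction_id,mean,ci_lower,ci_upper\n"
                        "R1,1.5,1.0,2.0\nR2,0.1,0.0,0.3\n")
        exp = read_experimental_fluxes(path, strain_id="wt")
        assert exp.reaction_ids == ["R1", "R2"]
        assert exp.interval("R1") == (1.0, 2.0)
        assert exp.strain_id == "wt"

    def test_mean_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="does not contain"):
            make_experimental([("r", 5.0, 0.0, 1.0)])
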