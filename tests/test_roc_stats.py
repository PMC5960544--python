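"""ROC statistics: AUC routes, cutoff rule, permutation p, reconstruction."""

import numpy as np
import numpy.testing as npt
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nacradiomics.roc_stats import (
    GREATER,
    LESS,
    ConfusionTable,
    RocCurve,
    analyze_feature_table,
    auc_mann_whitney,
    auc_trapezoid,
    confusion_at,
    permutation_pvalue,
    reconstruct_confusion,
    topleft_cutoff,
)


class TestAucMannWhitney:
    def test_perfect_separation(self):
        r = auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0 and r.direction == GREATER

    def test_all_ties_give_half(self):
        r = auc_mann_whitney([1, 1, 2, 2], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_reflection_for_low_scoring_positives(self):
        r = auc_mann_whitney([1, 2, 3, 4], [1, 1, 0, 0])
        assert r.auc_raw == 0.0
        assert r.auc == 1.0 and r.direction == LESS

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])

    def test_matches_trapezoid_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(200):
            n = int(rng.integers(4, 25))
            y = np.zeros(n, int)
            y[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if y.min() == y.max():
                continue
            x = np.round(rng.normal(size=n), 1)  # ties likely
            r = auc_mann_whitney(x, y)
            curve = RocCurve.from_scores(x, y, r.direction)
            assert abs(r.auc - auc_trapezoid(curve)) < 1e-12
            assert r.auc_raw == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=20,
                    unique=True))
    def test_invariant_under_monotone_transform(self, scores):
        x = np.asarray(scores, dtype=float) / 40.0
        y = (np.arange(x.size) % 2).astype(int)
        a = auc_mann_whitney(x, y)
        b = auc_mann_whitney(np.exp(x / 25.0), y)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.direction == b.direction


class TestTopleftCutoff:
    def test_perfect_separation_midpoint(self):
        curve = RocCurve.from_scores([1, 2, 3, 4], [0, 0, 1, 1], GREATER)
        cutoff, sens, spec = topleft_cutoff(curve)
        assert (sens, spec) == (1.0, 1.0)
        assert cutoff == 2.5

    def test_tie_broken_toward_higher_specificity(self):
        # operating points include (sens=1, spec=0.5) and (sens=0.5, spec=1),
        # both at squared distance 0.25 from the corner
        curve = RocCurve.from_scores([1, 2, 3, 4], [0, 1, 0, 1], GREATER)
        cutoff, sens, spec = topleft_cutoff(curve)
        assert (sens, spec) == (0.5, 1.0)
        assert cutoff == 3.5

    def test_two_point_case_reaches_zero_distance(self):
        curve = RocCurve.from_scores([1.0, 5.0], [0, 1], GREATER)
        cutoff, sens, spec = topleft_cutoff(curve)
        assert (sens, spec) == (1.0, 1.0) and 1.0 < cutoff < 5.0

    def test_literal_maximize_picks_farthest_operating_point(self):
        curve = RocCurve.from_scores([1, 2, 3, 4], [0, 0, 1, 1], GREATER)
        _, sens, spec = topleft_cutoff(curve, literal_maximize=True)
        # farthest attainable point from (1,1) is a curve endpoint at
        # distance 1; the higher-specificity tie rule picks (sens=0, spec=1)
        assert (1 - sens) ** 2 + (1 - spec) ** 2 == pytest.approx(1.0)
        assert (sens, spec) == (0.0, 1.0)

    def test_less_direction_cutoff_calls_below(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1, 1, 0, 0])
        r = auc_mann_whitney(scores, y)
        curve = RocCurve.from_scores(scores, y, r.direction)
        cutoff, sens, spec = topleft_cutoff(curve)
        assert (sens, spec) == (1.0, 1.0)
        _, rates = confusion_at(scores, y, cutoff, r.direction)
        assert rates["sens"] == 1.0 and rates["spec"] == 1.0


class TestConfusionAt:
    def test_reported_row_arithmetic(self):
        # tp=5, fp=7, tn=52, fn=5
        tab = ConfusionTable(tp=5, fp=7, tn=52, fn=5)
        r = tab.rates()
        assert r["sens"] == pytest.approx(0.50)
        assert r["spec"] == pytest.approx(52 / 59, abs=5e-4)  # ~0.881
        assert r["ppv"] == pytest.approx(5 / 12)   # ~0.417
        assert r["npv"] == pytest.approx(52 / 57)  # ~0.912
        assert r["acc"] == pytest.approx(57 / 69)  # ~0.826

    def test_all_negative_calls_have_undefined_ppv(self):
        scores = np.array([1.0, 2.0, 3.0])
        y = np.array([0, 1, 0])
        tab, r = confusion_at(scores, y, cutoff=10.0, direction=GREATER)
        assert (r["sens"], r["spec"]) == (0.0, 1.0)
        assert np.isnan(r["ppv"])

    def test_cutoff_below_all_scores(self):
        scores = np.array([1.0, 2.0, 3.0])
        y = np.array([0, 1, 0])
        _, r = confusion_at(scores, y, cutoff=0.0, direction=GREATER)
        assert (r["sens"], r["spec"]) == (1.0, 0.0)


class TestPermutationPvalue:
    def test_exhaustive_enumeration_by_hand(self):
        # 6 labelings of 2 positives among 4; only the two extreme ones
        # reach |AUC - 0.5| = 0.5
        p = permutation_pvalue([1, 2, 3, 4], [0, 0, 1, 1], n_perm=1000)
        assert p == pytest.approx(2 / 6)

    def test_auc_exactly_half_gives_p_one(self):
        p = permutation_pvalue([1, 1, 2, 2], [0, 1, 0, 1], n_perm=200)
        assert p == 1.0

    def test_sampled_p_bounded_below(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(8, 1, 10)])
        y = np.array([0] * 30 + [1] * 10)
        p = permutation_pvalue(x, y, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_exhaustive_and_sampled_agree(self, rng):
        x = rng.normal(size=9)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1])  # C(9,4) = 126 labelings
        exact = permutation_pvalue(x, y, n_perm=1000, seed=0)
        sampled = permutation_pvalue(x, y, n_perm=100, seed=0)
        assert sampled == pytest.approx(exact, abs=4 / np.sqrt(100))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2], [1, 1])


class TestReconstructConfusion:
    @pytest.mark.parametrize("sens, spec, expected", [
        ((0.50), 0.88, (5, 7, 52, 5)),   # 0.88*59 = 51.92 -> 52
        (0.70, 0.83, (7, 10, 49, 3)),    # PPV 7/17 ~ 0.41
        (1.0, 1.0, (10, 0, 59, 0)),
    ])
    def test_rounding_rule(self, sens, spec, expected):
        tab = reconstruct_confusion(sens, spec, 10, 59)
        assert (tab.tp, tab.fp, tab.tn, tab.fn) == expected

    def test_half_up_rounding(self):
        tab = reconstruct_confusion(0.55, 0.5, 10, 2)
        assert tab.tp == 6  # 5.5 rounds up
        assert tab.tn == 1

    def test_round_trip_property(self, rng):
        for _ in range(50):
            n_pos = int(rng.integers(3, 40))
            n_neg = int(rng.integers(3, 80))
            sens = rng.uniform(0, 1)
            spec = rng.uniform(0, 1)
            tab = reconstruct_confusion(sens, spec, n_pos, n_neg)
            r = tab.rates()
            assert abs(r["sens"] - sens) <= 0.5 / n_pos + 1e-12
            assert abs(r["spec"] - spec) <= 0.5 / n_neg + 1e-12

    def test_valid_rates_do_not_warn(self):
        # half-up rounding always lands within half a count of the input
        # rates, so well-formed inputs must reconstruct silently
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            reconstruct_confusion(0.33, 0.57, 10, 59)


class TestAnalyzeFeatureTable:
    def _toy(self, rng, n=24):
        import pandas as pd

        y = np.array([0] * (n // 2) + [1] * (n - n // 2))
        df = pd.DataFrame({
            "signal": rng.normal(size=n) + 2.5 * y,
            "noise": rng.normal(size=n),
            "constant": np.ones(n),
        })
        return df, y

    def test_reports_sorted_and_constant_skipped(self, rng):
        df, y = self._toy(rng)
        reports, frame = analyze_feature_table(df, y, n_perm=500, seed=0)
        names = [r.feature_name for r in reports]
        assert "constant" not in names
        assert names[0] == "signal"
        assert reports[0].significant
        assert list(frame["p_perm"]) == sorted(frame["p_perm"])

    def test_missing_values_dropped_per_feature(self, rng):
        df, y = self._toy(rng)
        df.loc[df.index[:3], "noise"] = np.nan
        reports, _ = analyze_feature_table(df, y, n_perm=200, seed=0)
        by_name = {r.feature_name: r for r in reports}
        assert by_name["noise"].n_missing == 3
        assert by_name["noise"].n_pos + by_name["noise"].n_neg == len(df) - 3

    def test_single_class_endpoint_aborts(self, rng):
        df, _ = self._toy(rng)
        with pytest.raises(ValueError, match="single-class"):
            analyze_feature_table(df, np.ones(len(df), int), n_perm=100)

    def test_report_rates_consistent_with_cutoff(self, rng):
        df, y = self._toy(rng)
        reports, _ = analyze_feature_table(df, y, n_perm=200, seed=0)
        for r in reports:
            x = df[r.feature_name].to_numpy()
            _, rates = confusion_at(x, y, r.cutoff, r.direction)
            assert rates["sens"] == pytest.approx(r.sens)
            assert rates["spec"] == pytest.approx(r.spec)

    def test_benjamini_hochberg_column_optional(self, rng):
        df, y = self._toy(rng)
        _, frame = analyze_feature_table(df, y, n_perm=200, seed=0,
                                         benjamini_hochberg=True)
        assert "q_value" in frame.columns
        assert (frame["q_value"] >= frame["p_perm"] - 1e-12).all()
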