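"""Metric battery and comparison statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from cardiossl.stats import (AnovaResult, ConfusionCounts, build_report,
                             confusion_from_predictions, confusion_metrics,
                             one_way_anova, roc_auc, tukey_hsd)

import pandas as pd


class TestConfusionMetrics:
    def test_hand_worked_example(self):
        m = confusion_metrics(ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(9 / 11)
        assert m.f_score == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert (m.sensitivity, m.specificity, m.precision, m.f_score) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_is_na_not_zero(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert np.isnan(m.precision)
        assert m.specificity == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_exhaustive_small_grid_matches_brute_force(self):
        """Every confusion table with counts <= 5 matches the raw formulas."""
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            for got, num, den in ((m.sensitivity, tp, tp + fn),
                                  (m.specificity, tn, tn + fp),
                                  (m.precision, tp, tp + fp)):
                if den == 0:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(num / den)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0
        assert pts["tpr"].iloc[-1] == 1.0 and pts["fpr"].iloc[-1] == 1.0

    def test_all_tied_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        """Midrank AUC equals the correctly-ordered-pairs count on 100
        random instances, and sklearn's implementation."""
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # force some ties
            auc, _ = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(brute, abs=1e-10)
            assert auc == pytest.approx(roc_auc_score(labels, scores),
                                        abs=1e-10)


class TestAnova:
    def test_equal_means_give_small_f(self, rng):
        g = rng.standard_normal(50)
        res = one_way_anova([g, g + 0.0, g.copy()])
        assert res.f == pytest.approx(0.0, abs=1e-20)

    def test_decomposition_identity(self, rng):
        groups = [rng.standard_normal(rng.integers(3, 12)) for _ in range(4)]
        res = one_way_anova(groups)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within,
                                             abs=1e-9)

    def test_two_groups_f_equals_t_squared(self, rng):
        """For k=2, ANOVA F equals the squared pooled-variance t statistic."""
        for _ in range(100):
            a = rng.standard_normal(int(rng.integers(3, 15)))
            b = rng.standard_normal(int(rng.integers(3, 15))) + rng.random()
            res = one_way_anova([a, b])
            t, p = sps.ttest_ind(a, b, equal_var=True)
            assert res.f == pytest.approx(t ** 2, rel=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            groups = [rng.standard_normal(int(rng.integers(3, 10)))
                      for _ in range(k)]
            res = one_way_anova(groups)
            f_ref, p_ref = sps.f_oneway(*groups)
            assert res.f == pytest.approx(f_ref, rel=1e-8)
            assert res.p == pytest.approx(p_ref, abs=1e-8)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [2.0, 2.0]])


class TestTukey:
    def test_identical_means_q_zero_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        res = tukey_hsd([g, g.copy(), g + 5])
        row = res.table.iloc[0]
        assert row["q"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_significance_flag_consistency(self, rng):
        """q > q_crit iff |mean diff| > HSD (balanced designs)."""
        for _ in range(20):
            k = int(rng.integers(3, 6))
            n = int(rng.integers(3, 8))
            groups = [rng.standard_normal(n) + rng.random() * 2
                      for _ in range(k)]
            res = tukey_hsd(groups)
            for _, row in res.table.iterrows():
                diff = abs(row["mean_i"] - row["mean_j"])
                assert row["significant_0.05"] == \
                    (diff > res.hsd_thresholds[0.05])

    def test_matches_scipy_tukey_hsd(self, rng):
        """Pairwise p-values match scipy's implementation on 50 balanced
        designs (k <= 5, n <= 10)."""
        for _ in range(50):
            k = int(rng.integers(3, 6))
            n = int(rng.integers(4, 11))
            groups = [rng.standard_normal(n) + rng.random() for _ in range(k)]
            res = tukey_hsd(groups)
            ref = sps.tukey_hsd(*groups)
            for idx, row in res.table.iterrows():
                i = int(row["group_i"][1:])
                j = int(row["group_j"][1:])
                assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_q_critical_matches_studentized_range(self):
        res = tukey_hsd([np.r_[1.0, 2, 3, 4], np.r_[2.0, 3, 4, 5],
                         np.r_[4.0, 5, 6, 7]])
        for alpha, q in res.q_critical.items():
            assert q == pytest.approx(
                sps.studentized_range.ppf(1 - alpha, 3, res.df_within),
                abs=1e-6)

    def test_p_monotone_in_q(self):
        """Larger studentized-range statistics give smaller p-values."""
        ps = [float(sps.studentized_range.sf(q, 4, 20)) for q in (1, 2, 3, 5)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBuildReport:
    @staticmethod
    def _cells():
        rows = []
        rng = np.random.default_rng(0)
        for task in ("noise", "rotation"):
            for red in (0.0, 0.5):
                for seed in range(3):
                    base = 0.9 - 0.2 * red + 0.02 * rng.random()
                    rows.append({
                        "task": task, "reduction": red, "seed": seed,
                        "val_acc": base, "test_acc": base,
                        "fgsm_drop": 0.1, "pgd_drop": 0.2,
                        "ood_score": 0.1,
                        "sensitivity": base, "specificity": base,
                        "precision": base, "f_score": base, "auc": base})
        return pd.DataFrame(rows)

    def test_summary_cardinality(self):
        report = build_report(self._cells())
        assert len(report["summary"]) == 4  # 2 tasks x 2 reductions

    def test_stats_block_groups_by_reduction(self):
        report = build_report(self._cells())
        assert report["stats"]["grouping"] == "reduction"
        assert report["stats"]["anova"]["df_between"] == 1
        assert report["stats"]["anova"]["p"] < 0.05

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            build_report(pd.DataFrame({"task": ["noise"]}))
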