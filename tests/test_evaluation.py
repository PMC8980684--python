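"""Statistical toolkit: confusion metrics, AUC, agreement, strata, screening."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctffr.errors import ValidationError
from ctffr.evaluation import (
    ConfusionMatrix,
    ThresholdPolicy,
    accuracy_by_ffr_bin,
    auc_mann_whitney,
    bland_altman,
    confusion_matrix,
    diagnostic_metrics,
    evaluate_cohort,
    group_compare,
    misdiagnosis_rates,
    paired_metric_compare,
    pearson_r,
    round_half_up,
    univariate_logistic_or,
)

# per-vessel confusion matrices reconstructed from the trial's printed
# fractions: index test sensitivity 152/169 with specificity 173/197, and
# the angiographic comparator 151/169 with 70/197
CM_INDEX = ConfusionMatrix(tp=152, fp=24, tn=173, fn=17)
CM_CTA = ConfusionMatrix(tp=151, fp=127, tn=70, fn=18)


def make_cohort(ffr, ct, cta=None):
    n = len(ffr)
    return pd.DataFrame(
        {"measured_ffr": ffr, "ct_ffr": ct,
         "cta_percent_stenosis": cta if cta is not None else np.full(n, 60.0)}
    )


class TestConfusionMatrix:
    def test_reconstructed_trial_matrix(self):
        truth = np.r_[np.ones(169, bool), np.zeros(197, bool)]
        positive = np.r_[np.ones(152, bool), np.zeros(17, bool),
                         np.ones(24, bool), np.zeros(173, bool)]
        assert confusion_matrix(positive, truth) == CM_INDEX

    def test_all_positive_all_ischemic(self):
        cm = confusion_matrix([True] * 5, [True] * 5)
        assert cm.fp == cm.tn == 0 and cm.tp == 5

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(11)
        pos = rng.random(20) < 0.5
        truth = rng.random(20) < 0.5
        cm = confusion_matrix(pos, truth)
        cells = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for p, t in zip(pos, truth):
            cells[("t" if p == t else "f") + ("p" if p else "n")] += 1
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (
            cells["tp"], cells["fp"], cells["tn"], cells["fn"]
        )

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix([], [])


class TestDiagnosticMetrics:
    def test_index_test_metrics_match_printed_values(self):
        rep = diagnostic_metrics(CM_INDEX)
        assert rep.sensitivity.rounded == 89.9
        assert rep.specificity.rounded == 87.8
        assert rep.accuracy.rounded == 88.8
        assert rep.npv.rounded == 91.1

    def test_comparator_metrics_match_printed_values(self):
        rep = diagnostic_metrics(CM_CTA)
        assert rep.specificity.rounded == 35.5
        assert rep.accuracy.rounded == 60.4
        assert rep.ppv.rounded == 54.3

    def test_perfect_classifier(self):
        rep = diagnostic_metrics(ConfusionMatrix(tp=30, fp=0, tn=40, fn=0))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            m = getattr(rep, name)
            assert m.value_pct == 100.0
            assert m.ci_high_pct <= 100.0 + 1e-9

    def test_wilson_ci_contains_estimate_and_is_bounded(self):
        for cm in (CM_INDEX, CM_CTA, ConfusionMatrix(1, 1, 1, 1)):
            rep = diagnostic_metrics(cm)
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
                m = getattr(rep, name)
                assert 0.0 <= m.ci_low_pct <= m.value_pct <= m.ci_high_pct <= 100.0

    def test_zero_denominator_flagged_undefined(self):
        rep = diagnostic_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5))
        assert not rep.ppv.defined and rep.sensitivity.defined

    def test_accuracy_identity(self):
        """accuracy = (se*P + sp*N) / (P+N) for any confusion matrix."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            rep = diagnostic_metrics(ConfusionMatrix(int(tp), int(fp), int(tn), int(fn)))
            p, n = tp + fn, tn + fp
            lhs = rep.accuracy.value_pct
            rhs = (rep.sensitivity.value_pct * p + rep.specificity.value_pct * n) / (p + n)
            assert lhs == pytest.approx(rhs, rel=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        scores = np.r_[np.linspace(0.2, 0.5, 6), np.linspace(0.8, 0.95, 6)]
        truth = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        assert auc_mann_whitney(scores, truth).auc == 1.0

    def test_identical_scores_give_half(self):
        res = auc_mann_whitney(np.full(10, 0.8), np.r_[np.ones(5, bool), np.zeros(5, bool)])
        assert res.auc == 0.5

    def test_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.random(12), 1)  # ties likely
        truth = rng.random(12) < 0.5
        truth[0], truth[1] = True, False  # both classes present
        res = auc_mann_whitney(scores, truth)
        num, total = 0.0, 0
        for sd in scores[truth]:
            for sn in scores[~truth]:
                total += 1
                num += 1.0 if sn > sd else (0.5 if sn == sd else 0.0)
        assert res.auc == pytest.approx(num / total, rel=1e-12)

    def test_binary_score_auc_equals_mean_of_se_sp(self):
        rng = np.random.default_rng(13)
        truth = rng.random(200) < 0.45
        positive = truth ^ (rng.random(200) < 0.25)  # noisy classifier
        cm = confusion_matrix(positive, truth)
        rep = diagnostic_metrics(cm)
        res = auc_mann_whitney(-positive.astype(float), truth)
        expected = (rep.sensitivity.value_pct + rep.specificity.value_pct) / 200.0
        assert res.auc == pytest.approx(expected, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([0.5, 0.6], [True, True])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert res.mean_difference == 0.0 and res.sd == 0.0

    def test_constant_offset(self):
        x = np.array([0.7, 0.8, 0.9])
        res = bland_altman(x, x + 0.05)
        assert res.mean_difference == pytest.approx(0.05)
        assert res.sd == pytest.approx(0.0, abs=1e-15)

    def test_matches_hand_computation(self):
        x = np.array([0.70, 0.75, 0.80, 0.85, 0.90])
        y = np.array([0.72, 0.74, 0.83, 0.84, 0.93])
        d = y - x
        res = bland_altman(x, y)
        assert res.mean_difference == pytest.approx(d.mean())
        assert res.sd == pytest.approx(d.std(ddof=1))
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-3)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), rel=1e-3)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([0.8], [0.7])


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([0.1, 0.4, 0.7, 0.9])
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_definition_oracle(self):
        x = np.array([0.62, 0.71, 0.80, 0.85, 0.90, 0.95])
        y = np.array([0.60, 0.75, 0.74, 0.88, 0.87, 0.99])
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std(ddof=0) * y.std(ddof=0)
        )
        assert pearson_r(x, y).r == pytest.approx(r_oracle, rel=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson_r([1.0, 1.0, 1.0], [0.2, 0.3, 0.4])
        assert not res.defined


class TestBinAccuracy:
    def test_gray_zone_bin_from_stratum_counts(self):
        """40 concordant of 50 gray-zone vessels -> 80.0% accuracy."""
        ffr = np.full(50, 0.78)
        ct = np.r_[np.full(40, 0.74), np.full(10, 0.85)]
        table = accuracy_by_ffr_bin(make_cohort(ffr, ct))
        row = table[table["bin"] == "0.76-0.80"].iloc[0]
        assert row["n"] == 50 and row["accuracy_pct"] == 80.0

    def test_perfect_agreement_everywhere(self):
        rng = np.random.default_rng(2)
        ffr = rng.uniform(0.3, 0.99, 300)
        table = accuracy_by_ffr_bin(make_cohort(ffr, ffr))
        nonempty = table[table["n"] > 0]
        assert (nonempty["accuracy_pct"] == 100.0).all()

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(8)
        ffr = rng.uniform(0.3, 0.99, 200)
        ct = np.clip(ffr + rng.normal(0, 0.05, 200), 0.01, 1.0)
        table = accuracy_by_ffr_bin(make_cohort(ffr, ct))
        for _, row in table.iterrows():
            mask = (ffr >= row["lo"]) & (ffr < row["hi"])
            assert row["n"] == int(mask.sum())
            if row["n"]:
                oracle = 100.0 * np.mean((ct[mask] <= 0.8) == (ffr[mask] < 0.8))
                assert row["accuracy_pct"] == round_half_up(oracle, 1)

    def test_bins_partition_unit_interval(self):
        rng = np.random.default_rng(1)
        ffr = rng.uniform(0.01, 1.0, 500)
        table = accuracy_by_ffr_bin(make_cohort(ffr, ffr))
        assert table["n"].sum() == 500


class TestMisdiagnosisRates:
    def test_trial_stratum_rates(self):
        """7/119 FN below the gray zone, 10/50 FN inside it, 21/197 FP above."""
        ffr = np.r_[np.full(119, 0.70), np.full(50, 0.78), np.full(197, 0.90)]
        ct = np.r_[
            np.full(112, 0.70), np.full(7, 0.85),   # low stratum: 7 FN
            np.full(40, 0.74), np.full(10, 0.85),   # gray zone: 10 FN
            np.full(176, 0.90), np.full(21, 0.75),  # non-ischemic: 21 FP
        ]
        table = misdiagnosis_rates(make_cohort(ffr, ct)).set_index("stratum")
        assert table.loc["low", "rate_pct"] == 5.9
        assert table.loc["gray", "rate_pct"] == 20.0
        assert table.loc["gray", "accuracy_pct"] == 80.0
        assert table.loc["high", "rate_pct"] == 10.7

    def test_empty_stratum_undefined(self):
        ffr = np.full(10, 0.9)
        table = misdiagnosis_rates(make_cohort(ffr, ffr)).set_index("stratum")
        assert np.isnan(table.loc["gray", "rate_pct"])
        assert table.loc["high", "rate_pct"] == 0.0


class TestGroupCompare:
    def test_identical_multisets_symmetric(self):
        vals = np.r_[[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]
        labels = np.r_[np.zeros(3), np.ones(3)]
        res = group_compare(vals, labels, "continuous")
        assert res.p >= 0.99

    def test_u_statistic_matches_enumeration(self):
        a, b = np.array([1.2, 3.4, 2.2]), np.array([0.5, 2.9, 4.0])
        res = group_compare(np.r_[a, b], np.r_[np.zeros(3), np.ones(3)], "continuous")
        u_oracle = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.statistic == pytest.approx(u_oracle)

    def test_fisher_path_matches_hypergeometric_sum(self):
        # 2x2 with a zero cell forces the exact test
        a = np.r_[np.ones(6, bool), np.zeros(0, bool)]
        b = np.r_[np.ones(2, bool), np.zeros(5, bool)]
        res = group_compare(np.r_[a, b], np.r_[np.zeros(6), np.ones(7)], "categorical")
        assert res.method == "fisher-exact"
        # two-sided Fisher p as a sum of hypergeometric probabilities
        m = stats.hypergeom(13, 8, 6)
        p_obs = m.pmf(6)
        p_oracle = sum(m.pmf(k) for k in range(max(0, 1), 7) if m.pmf(k) <= p_obs + 1e-12)
        assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([1, 2, 3], [0, 0, 0], "continuous")


class TestLogisticOR:
    def test_binary_covariate_matches_cross_product_ratio(self):
        # 2x2 table: a=30 exposed cases, b=20 exposed controls, c=10, d=40
        x = np.r_[np.ones(30), np.ones(20), np.zeros(10), np.zeros(40)]
        y = np.r_[np.ones(30), np.zeros(20), np.ones(10), np.zeros(40)]
        res = univariate_logistic_or(x, y)
        assert res.estimable
        assert res.odds_ratio == pytest.approx((30 * 40) / (20 * 10), rel=1e-4)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 5000)
        y = rng.random(5000) < 0.3
        res = univariate_logistic_or(x, y)
        assert 0.9 < res.odds_ratio < 1.1

    def test_constant_covariate_non_estimable(self):
        res = univariate_logistic_or(np.ones(20), np.r_[np.ones(10), np.zeros(10)])
        assert not res.estimable

    def test_complete_separation_flagged(self):
        x = np.r_[np.linspace(2, 3, 10), np.linspace(-3, -2, 10)]
        y = np.r_[np.ones(10), np.zeros(10)]
        res = univariate_logistic_or(x, y)
        assert not res.estimable


class TestMcNemar:
    def test_identical_classifiers_p_one(self):
        truth = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        pos = truth.copy()
        assert paired_metric_compare(truth, pos, pos, "sensitivity") == 1.0

    def test_discordant_12_3_matches_binomial_sum(self):
        truth = np.ones(40, bool)
        a = np.r_[np.zeros(12, bool), np.ones(3, bool), np.ones(25, bool)]
        b = np.r_[np.ones(12, bool), np.zeros(3, bool), np.ones(25, bool)]
        p = paired_metric_compare(truth, a, b, "sensitivity")
        oracle = 2.0 * sum(stats.binom.pmf(k, 15, 0.5) for k in range(0, 4))
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_symmetric_discordance_p_one(self):
        truth = np.ones(10, bool)
        a = np.r_[np.zeros(3, bool), np.ones(3, bool), np.ones(4, bool)]
        b = np.r_[np.ones(3, bool), np.zeros(3, bool), np.ones(4, bool)]
        assert paired_metric_compare(truth, a, b, "sensitivity") == pytest.approx(1.0)


class TestFullPipeline:
    def test_exact_index_test_scores_perfectly(self):
        """When CT-FFR equals measured FFR every metric is 100%."""
        rng = np.random.default_rng(31)
        ffr = rng.uniform(0.35, 0.99, 400)
        cta = np.where(ffr < 0.8, 75.0, 35.0)
        df = make_cohort(ffr, ffr, cta)
        df["calcium_score"] = rng.uniform(0, 400, 400)
        report = evaluate_cohort(df)
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(report.ct_ffr, name).value_pct == 100.0
        assert report.ct_ffr.auc.auc == 1.0
        nonempty = report.bin_accuracy[report.bin_accuracy["n"] > 0]
        assert (nonempty["accuracy_pct"] == 100.0).all()
        assert report.correlation.r == pytest.approx(1.0)

    def test_policy_strata_partition(self):
        policy = ThresholdPolicy()
        ffr = np.array([0.5, 0.759999, 0.76, 0.799999, 0.8, 0.95])
        assert list(policy.stratum(ffr)) == ["low", "low", "gray", "gray", "high", "high"]
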