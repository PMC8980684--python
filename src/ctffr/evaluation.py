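"""Diagnostic-performance analysis of a per-vessel trial table.

Implements the trial's statistical toolkit: 2x2 confusion-matrix metrics
with Wilson confidence intervals, rank-based AUC with a DeLong-style
interval, Pearson correlation, Bland-Altman agreement, diagnostic accuracy
per FFR bin, stratified misdiagnosis rates around the gray zone,
Mann-Whitney / chi-square / Fisher group comparisons, univariate logistic
risk-factor screening, and McNemar paired comparison of two classifiers.

Conventions follow the printed trial tables: ischemia is FFR < 0.80, the
index test is positive when CT-FFR <= 0.80, CTA is positive at >= 50%
stenosis, and the gray zone [0.76, 0.80) is part of the ischemic class.
Percentages are reported rounded half-up to one decimal.  No multiple-
testing correction is applied (flagged in the report).
"""
from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table printing)."""
    if not np.isfinite(x):
        return float(x)
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ThresholdPolicy:
    """Classification rules of the trial."""

    ffr_threshold: float = 0.80  # ischemia: FFR < threshold
    ct_ffr_threshold: float = 0.80  # index positive: CT-FFR <= threshold
    cta_threshold: float = 50.0  # CTA positive: percent stenosis >= threshold
    gray_low: float = 0.76
    gray_high: float = 0.80  # gray zone [low, high), subset of ischemic

    def __post_init__(self):
        if not (0.0 < self.ffr_threshold < 1.0 and 0.0 < self.ct_ffr_threshold < 1.0):
            raise ValidationError("FFR thresholds must lie in (0, 1)")
        if not (0.0 < self.cta_threshold < 100.0):
            raise ValidationError("CTA threshold must lie in (0, 100)")
        if not (0.0 < self.gray_low < self.gray_high <= self.ffr_threshold):
            raise ValidationError("gray zone must sit just below the FFR threshold")

    def ischemic(self, ffr) -> np.ndarray:
        return np.asarray(ffr, dtype=float) < self.ffr_threshold

    def ct_positive(self, ct_ffr) -> np.ndarray:
        return np.asarray(ct_ffr, dtype=float) <= self.ct_ffr_threshold

    def cta_positive(self, percent_stenosis) -> np.ndarray:
        return np.asarray(percent_stenosis, dtype=float) >= self.cta_threshold

    def stratum(self, ffr) -> np.ndarray:
        """'low' (< gray_low), 'gray' [gray_low, gray_high), 'high' (rest)."""
        f = np.asarray(ffr, dtype=float)
        out = np.where(f < self.gray_low, "low", np.where(f < self.gray_high, "gray", "high"))
        return out


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_flags(cls, index_positive, ischemic) -> "ConfusionMatrix":
        pos = np.asarray(index_positive, dtype=bool)
        truth = np.asarray(ischemic, dtype=bool)
        if pos.size == 0 or pos.shape != truth.shape:
            raise ValidationError("flags must be equal-length and non-empty")
        return cls(
            tp=int(np.sum(pos & truth)),
            fp=int(np.sum(pos & ~truth)),
            tn=int(np.sum(~pos & ~truth)),
            fn=int(np.sum(~pos & truth)),
        )


def confusion_matrix(index_positive, ischemic) -> ConfusionMatrix:
    return ConfusionMatrix.from_flags(index_positive, ischemic)


@dataclass(frozen=True)
class MetricCI:
    """A proportion-type metric in percent with its 95% CI."""

    value_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int
    denominator: int
    defined: bool = True

    @property
    def rounded(self) -> float:
        return round_half_up(self.value_pct, 1)


@dataclass
class DiagnosticReport:
    sensitivity: MetricCI
    specificity: MetricCI
    accuracy: MetricCI
    ppv: MetricCI
    npv: MetricCI
    auc: "AUCResult | None" = None

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            m: MetricCI = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "value_pct": m.rounded if m.defined else np.nan,
                    "ci_low_pct": round_half_up(m.ci_low_pct, 1) if m.defined else np.nan,
                    "ci_high_pct": round_half_up(m.ci_high_pct, 1) if m.defined else np.nan,
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                }
            )
        if self.auc is not None:
            rows.append(
                {
                    "metric": "auc",
                    "value_pct": self.auc.auc,
                    "ci_low_pct": self.auc.ci_low,
                    "ci_high_pct": self.auc.ci_high,
                    "numerator": np.nan,
                    "denominator": np.nan,
                }
            )
        return pd.DataFrame(rows)


def _proportion_metric(num: int, den: int, ci_method: str) -> MetricCI:
    if den == 0:
        return MetricCI(np.nan, np.nan, np.nan, num, den, defined=False)
    lo, hi = proportion_confint(num, den, alpha=0.05, method=ci_method)
    return MetricCI(100.0 * num / den, 100.0 * lo, 100.0 * hi, num, den)


def diagnostic_metrics(cm: ConfusionMatrix, ci_method: str = "wilson") -> DiagnosticReport:
    """Sensitivity/specificity/accuracy/PPV/NPV with 95% CIs.

    Wilson score intervals by default (``ci_method='normal'`` for the Wald
    approximation).  A metric with a zero denominator is flagged undefined
    rather than fabricated.
    """
    if ci_method not in ("wilson", "normal"):
        raise ValidationError("ci_method must be 'wilson' or 'normal'")
    return DiagnosticReport(
        sensitivity=_proportion_metric(cm.tp, cm.tp + cm.fn, ci_method),
        specificity=_proportion_metric(cm.tn, cm.tn + cm.fp, ci_method),
        accuracy=_proportion_metric(cm.tp + cm.tn, cm.total, ci_method),
        ppv=_proportion_metric(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_proportion_metric(cm.tn, cm.tn + cm.fn, ci_method),
    )


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_diseased: int
    n_nondiseased: int


def auc_mann_whitney(scores, ischemic) -> AUCResult:
    """Rank-based (concordance) AUC with ties counted 1/2.

    ``scores`` are oriented so that LOWER values indicate disease (as for
    an FFR-like index).  The 95% CI uses the DeLong placement variance.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(ischemic, dtype=bool)
    if s.shape != d.shape or s.size == 0:
        raise ValidationError("scores and flags must be equal-length and non-empty")
    n1 = int(d.sum())
    n0 = int((~d).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    x = s[d]  # diseased
    y = s[~d]  # non-diseased
    # placements: for each diseased case, fraction of non-diseased scoring higher
    diff = y[None, :] - x[:, None]
    conc = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = conc.mean(axis=1)
    v01 = conc.mean(axis=0)
    auc = float(conc.mean())
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    half = 1.959963984540054 * np.sqrt(var)
    return AUCResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_diseased=n1,
        n_nondiseased=n0,
    )


@dataclass(frozen=True)
class BlandAltman:
    """Agreement of paired measurements: differences d = y - x."""

    mean_difference: float
    sd: float
    loa_low: float
    loa_high: float
    ci_mean_low: float
    ci_mean_high: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Mean difference, SD, 95% limits of agreement (mean +/- 1.96 SD) and
    the 95% CI of the mean difference (both reported; they answer different
    questions and differ by a factor ~sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need >= 2 equal-length pairs")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half_loa = 1.959963984540054 * sd
    half_ci = 1.959963984540054 * sd / np.sqrt(d.size)
    return BlandAltman(
        mean_difference=mean,
        sd=sd,
        loa_low=mean - half_loa,
        loa_high=mean + half_loa,
        ci_mean_low=mean - half_ci,
        ci_mean_high=mean + half_ci,
        n=int(d.size),
    )


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    defined: bool = True


def pearson_r(x, y) -> PearsonResult:
    """Product-moment correlation with t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need >= 3 equal-length pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return PearsonResult(np.nan, np.nan, int(x.size), defined=False)
    res = stats.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), int(x.size))


#: default FFR bin edges; half-open [lo, hi) except the last bin which is
#: closed at 1.0.  Labels follow 2-decimal clinical readings; the bin above
#: the gray zone starts at the 0.80 decision threshold.
DEFAULT_FFR_BINS: list[tuple[str, float, float]] = [
    ("<0.66", 0.0, 0.66),
    ("0.66-0.70", 0.66, 0.71),
    ("0.71-0.75", 0.71, 0.76),
    ("0.76-0.80", 0.76, 0.80),
    ("0.81-0.85", 0.80, 0.86),
    ("0.86-0.90", 0.86, 0.91),
    (">0.90", 0.91, 1.0 + 1e-12),
]


def accuracy_by_ffr_bin(
    cohort: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
    bins: Sequence[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-FFR-bin diagnostic accuracy of the CT-FFR classification.

    A vessel counts as correct when the CT-FFR call (<= / > threshold)
    agrees with the FFR call.  Empty bins get n = 0 and undefined accuracy.
    """
    policy = policy or ThresholdPolicy()
    bins = list(bins) if bins is not None else DEFAULT_FFR_BINS
    edges = [b[1] for b in bins] + [bins[-1][2]]
    if any(abs(edges[i + 1] - bins[i][2]) > 1e-12 for i in range(len(bins) - 1)):
        raise ValidationError("bins must be contiguous and partition (0, 1]")
    ffr = cohort["measured_ffr"].to_numpy(dtype=float)
    correct = policy.ct_positive(cohort["ct_ffr"]) == policy.ischemic(ffr)
    rows = []
    for label, lo, hi in bins:
        mask = (ffr >= lo) & (ffr < hi)
        n = int(mask.sum())
        acc = 100.0 * float(correct[mask].mean()) if n else np.nan
        rows.append(
            {"bin": label, "lo": lo, "hi": hi, "n": n,
             "accuracy_pct": round_half_up(acc, 1) if n else np.nan,
             "defined": bool(n)}
        )
    return pd.DataFrame(rows)


def misdiagnosis_rates(
    cohort: pd.DataFrame, policy: ThresholdPolicy | None = None
) -> pd.DataFrame:
    """Counts and misdiagnosis rates per FFR stratum around the gray zone.

    Strata: FFR < 0.76, gray zone [0.76, 0.80) (both ischemic: a CT-FFR >
    threshold there is a false negative), and FFR >= 0.80 (a CT-FFR <=
    threshold is a false positive).
    """
    policy = policy or ThresholdPolicy()
    ffr = cohort["measured_ffr"].to_numpy(dtype=float)
    positive = policy.ct_positive(cohort["ct_ffr"])
    strata = policy.stratum(ffr)
    rows = []
    for name, kind in (("low", "FN"), ("gray", "FN"), ("high", "FP")):
        mask = strata == name
        n = int(mask.sum())
        miss = int(np.sum(~positive[mask])) if kind == "FN" else int(np.sum(positive[mask]))
        rate = 100.0 * miss / n if n else np.nan
        rows.append(
            {
                "stratum": name,
                "error_kind": kind,
                "n": n,
                "misdiagnosed": miss,
                "rate_pct": round_half_up(rate, 1) if n else np.nan,
                "accuracy_pct": round_half_up(100.0 - rate, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p: float
    method: str
    summary: pd.DataFrame  # per-group median/IQR or counts


def group_compare(values, group_labels, kind: str = "continuous") -> GroupComparison:
    """Two-group comparison as in the trial's covariate tables.

    ``continuous``: Mann-Whitney U (tie-corrected normal approximation,
    no continuity correction) with per-group median and IQR.
    ``categorical``: chi-square on the 2x2 table, or Fisher's exact test
    when any expected cell count is < 5.
    """
    values = np.asarray(values)
    groups = np.asarray(group_labels)
    if values.shape != groups.shape:
        raise ValidationError("values and group labels must be equal-length")
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValidationError("need exactly two groups")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        summary = pd.DataFrame(
            {
                "group": names,
                "n": [a.size, b.size],
                "median": [np.median(a), np.median(b)],
                "q1": [np.percentile(a, 25), np.percentile(b, 25)],
                "q3": [np.percentile(a, 75), np.percentile(b, 75)],
            }
        )
        return GroupComparison(float(res.statistic), float(res.pvalue),
                               "mann-whitney", summary)
    if kind == "categorical":
        va = np.asarray(a, dtype=bool)
        vb = np.asarray(b, dtype=bool)
        table = np.array(
            [[int(va.sum()), int((~va).sum())], [int(vb.sum()), int((~vb).sum())]]
        )
        summary = pd.DataFrame(
            {"group": names, "n": [va.size, vb.size],
             "positive": [int(va.sum()), int(vb.sum())]}
        )
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValidationError("degenerate 2x2 table")
        expected = stats.contingency.expected_freq(table)
        if np.any(expected < 5):
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return GroupComparison(float(odds), float(p), "fisher-exact", summary)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(float(chi2), float(p), "chi-square", summary)
    raise ValidationError("kind must be 'continuous' or 'categorical'")


@dataclass(frozen=True)
class LogisticOR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    estimable: bool = True
    note: str = ""


def univariate_logistic_or(covariate, outcome) -> LogisticOR:
    """Single-covariate logistic regression; OR = exp(slope), Wald CI and p.

    Complete separation or a constant covariate is flagged non-estimable
    instead of silently diverging.
    """
    import statsmodels.api as sm

    x = np.asarray(covariate, dtype=float)
    yy = np.asarray(outcome, dtype=bool).astype(float)
    if x.shape != yy.shape or x.size == 0:
        raise ValidationError("covariate and outcome must be equal-length, non-empty")
    if yy.min() == yy.max():
        raise ValidationError("outcome must contain both classes")
    if np.std(x) == 0:
        return LogisticOR(np.nan, np.nan, np.nan, np.nan, int(x.size),
                          estimable=False, note="constant covariate")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter is handled below
            fit = sm.Logit(yy, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and friends
        return LogisticOR(np.nan, np.nan, np.nan, np.nan, int(x.size),
                          estimable=False, note=str(exc))
    slope = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(se) or se > 50 or abs(slope) > 50 or not fit.mle_retvals["converged"]:
        return LogisticOR(np.nan, np.nan, np.nan, np.nan, int(x.size),
                          estimable=False, note="separation or non-convergence")
    ci = fit.conf_int()[1]
    return LogisticOR(
        odds_ratio=float(np.exp(slope)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p=float(fit.pvalues[1]),
        n=int(x.size),
    )


def paired_metric_compare(truth, positive_a, positive_b, on: str = "sensitivity") -> float:
    """McNemar exact p comparing two classifiers on the same vessels.

    ``on='sensitivity'`` restricts to truly ischemic vessels,
    ``on='specificity'`` to non-ischemic ones; the test acts on the
    discordant correct/incorrect pairs (exact binomial at 1/2).  With no
    discordant pairs p = 1.
    """
    t = np.asarray(truth, dtype=bool)
    a = np.asarray(positive_a, dtype=bool)
    b = np.asarray(positive_b, dtype=bool)
    if not (t.shape == a.shape == b.shape) or t.size == 0:
        raise ValidationError("flags must be equal-length and non-empty")
    if on == "sensitivity":
        mask = t
        correct_a, correct_b = a[mask], b[mask]
    elif on == "specificity":
        mask = ~t
        correct_a, correct_b = ~a[mask], ~b[mask]
    else:
        raise ValidationError("on must be 'sensitivity' or 'specificity'")
    n01 = int(np.sum(~correct_a & correct_b))
    n10 = int(np.sum(correct_a & ~correct_b))
    if n01 + n10 == 0:
        return 1.0
    table = [[0, n01], [n10, 0]]
    return float(_sm_mcnemar(table, exact=True).pvalue)


# ---------------------------------------------------------------------------
# whole-cohort report

#: lesion covariates screened in the stratified misdiagnosis analysis
DEFAULT_COVARIATES = (
    "calcium_score",
    "plaque_burden",
    "calcified_volume",
    "lumen_area",
    "lumen_diameter",
    "lesion_length",
)


@dataclass
class TrialReport:
    """All evaluation tables for one cohort; ``footer`` carries caveats."""

    ct_ffr: DiagnosticReport
    cta: DiagnosticReport
    mcnemar_sensitivity_p: float
    mcnemar_specificity_p: float
    correlation: PearsonResult
    agreement: BlandAltman
    agreement_by_stratum: pd.DataFrame
    bin_accuracy: pd.DataFrame
    misdiagnosis: pd.DataFrame
    odds_ratios: pd.DataFrame
    covariate_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    footer: str = "No multiple-testing correction applied."

    def summary(self) -> dict:
        return {
            "n_vessels": int(self.ct_ffr.accuracy.denominator),
            "ct_ffr_sensitivity_pct": self.ct_ffr.sensitivity.rounded,
            "ct_ffr_specificity_pct": self.ct_ffr.specificity.rounded,
            "ct_ffr_accuracy_pct": self.ct_ffr.accuracy.rounded,
            "ct_ffr_ppv_pct": self.ct_ffr.ppv.rounded,
            "ct_ffr_npv_pct": self.ct_ffr.npv.rounded,
            "ct_ffr_auc": self.ct_ffr.auc.auc if self.ct_ffr.auc else None,
            "cta_sensitivity_pct": self.cta.sensitivity.rounded,
            "cta_specificity_pct": self.cta.specificity.rounded,
            "cta_accuracy_pct": self.cta.accuracy.rounded,
            "cta_ppv_pct": self.cta.ppv.rounded,
            "cta_npv_pct": self.cta.npv.rounded,
            "pearson_r": self.correlation.r,
            "bland_altman_mean_difference": self.agreement.mean_difference,
            "mcnemar_sensitivity_p": self.mcnemar_sensitivity_p,
            "mcnemar_specificity_p": self.mcnemar_specificity_p,
            "footer": self.footer,
        }


def evaluate_cohort(
    cohort: pd.DataFrame,
    policy: ThresholdPolicy | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> TrialReport:
    """Run the complete per-vessel analysis on a trial table."""
    policy = policy or ThresholdPolicy()
    required = {"ct_ffr", "measured_ffr", "cta_percent_stenosis"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    ffr = cohort["measured_ffr"].to_numpy(dtype=float)
    ct = cohort["ct_ffr"].to_numpy(dtype=float)
    cta = cohort["cta_percent_stenosis"].to_numpy(dtype=float)
    truth = policy.ischemic(ffr)
    ct_pos = policy.ct_positive(ct)
    cta_pos = policy.cta_positive(cta)

    ct_report = diagnostic_metrics(confusion_matrix(ct_pos, truth))
    ct_report.auc = auc_mann_whitney(ct, truth)
    cta_report = diagnostic_metrics(confusion_matrix(cta_pos, truth))
    # binary CTA "score": lower oriented as more diseased for consistency
    cta_report.auc = auc_mann_whitney(-cta_pos.astype(float), truth)

    strata = policy.stratum(ffr)
    ba_rows = []
    for name in ("low", "gray", "high", "all"):
        mask = np.ones_like(truth) if name == "all" else strata == name
        if int(mask.sum()) >= 2:
            ba = bland_altman(ct[mask], ffr[mask])
            ba_rows.append(
                {"stratum": name, "n": ba.n, "mean_difference": ba.mean_difference,
                 "sd": ba.sd, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                 "ci_mean_low": ba.ci_mean_low, "ci_mean_high": ba.ci_mean_high}
            )

    # gray-zone burden comparisons: covariate medians/IQRs with Mann-Whitney
    # p for the stratum pairs flanking the gray zone
    cmp_rows = []
    for name_a, name_b in (("low", "gray"), ("gray", "high")):
        mask = (strata == name_a) | (strata == name_b)
        if len(set(strata[mask])) < 2:
            continue
        for cov in covariates:
            if cov not in cohort.columns:
                continue
            res = group_compare(
                cohort.loc[mask, cov].to_numpy(dtype=float), strata[mask], "continuous"
            )
            s = res.summary.set_index("group")
            cmp_rows.append(
                {"covariate": cov, "stratum_a": name_a, "stratum_b": name_b,
                 "median_a": s.loc[name_a, "median"], "median_b": s.loc[name_b, "median"],
                 "q1_a": s.loc[name_a, "q1"], "q3_a": s.loc[name_a, "q3"],
                 "q1_b": s.loc[name_b, "q1"], "q3_b": s.loc[name_b, "q3"],
                 "u_statistic": res.statistic, "p": res.p}
            )

    or_rows = []
    for stratum_name, kind in (("low", "FN"), ("gray", "FN"), ("high", "FP")):
        mask = strata == stratum_name
        if int(mask.sum()) == 0:
            continue
        outcome = (~ct_pos[mask]) if kind == "FN" else ct_pos[mask]
        for cov in covariates:
            if cov not in cohort.columns:
                continue
            x = cohort.loc[mask, cov].to_numpy(dtype=float)
            if outcome.min() == outcome.max():
                res = LogisticOR(np.nan, np.nan, np.nan, np.nan, int(mask.sum()),
                                 estimable=False, note="single-class outcome")
            else:
                res = univariate_logistic_or(x, outcome)
            or_rows.append(
                {"stratum": stratum_name, "error_kind": kind, "covariate": cov,
                 "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                 "ci_high": res.ci_high, "p": res.p, "estimable": res.estimable,
                 "note": res.note}
            )

    return TrialReport(
        ct_ffr=ct_report,
        cta=cta_report,
        mcnemar_sensitivity_p=paired_metric_compare(truth, cta_pos, ct_pos, "sensitivity"),
        mcnemar_specificity_p=paired_metric_compare(truth, cta_pos, ct_pos, "specificity"),
        correlation=pearson_r(ffr, ct),
        agreement=bland_altman(ct, ffr),
        agreement_by_stratum=pd.DataFrame(ba_rows),
        bin_accuracy=accuracy_by_ffr_bin(cohort, policy),
        misdiagnosis=misdiagnosis_rates(cohort, policy),
        odds_ratios=pd.DataFrame(or_rows),
        covariate_comparisons=pd.DataFrame(cmp_rows),
    )
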