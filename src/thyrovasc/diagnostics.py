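"""Diagnostic-accuracy statistics for single-operating-point binary tests.

Point metrics from the confusion matrix (sensitivity, specificity, PPV,
NPV, false-negative and false-positive rates, all in percent) carry exact
Clopper-Pearson binomial confidence intervals. Because every assessment
here is a binary test at one operating point, the AUROC is the trapezoidal
area (SEN + SPEC) / 2 on the [0, 1] scale, with a Hanley-McNeil standard
error for its interval.

Paired comparisons use the exact-binomial McNemar test (small discordant
counts are the norm at n = 94) or its continuity-corrected chi-square
variant, and Cochran's Q for three or more correlated classifiers. AUROCs
are compared with an (unpaired) z-test on Hanley-McNeil standard errors.
Rater agreement uses unweighted Cohen's kappa alongside the raw proportion
of agreement. No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats import contingency_tables as sm_tables

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "PerformanceReport",
    "TestResult",
    "confusion_matrix",
    "confusion_from_rates",
    "clopper_pearson",
    "hanley_mcneil_se",
    "performance",
    "mcnemar",
    "cochran_q",
    "auroc_z_test",
    "cohens_kappa",
    "paired_t_test",
    "proportion_chi_square",
    "round_half_away",
]

_LABELS = ("malignant", "benign")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (table-style, not banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with its confidence interval (same units)."""

    value: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    note: str | None = None


@dataclass(frozen=True)
class PerformanceReport:
    """All point metrics of one binary assessment, with CIs.

    Percent metrics are on the 0-100 scale; the AUROC on 0-1. PPV/NPV are
    None when their denominator is zero (no positive / no negative calls).
    """

    sen: MetricEstimate
    spec: MetricEstimate
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    fnr: MetricEstimate
    fpr: MetricEstimate
    auroc: MetricEstimate
    n_pos: int
    n_neg: int
    ci_level: float = field(default=0.95)


def confusion_matrix(
    predictions: Sequence[str], truths: Sequence[str]
) -> ConfusionMatrix:
    """Cross-tabulate malignant/benign predictions against truth labels."""
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths differ in length")
    for label in set(predictions.tolist()) | set(truths.tolist()):
        if label not in _LABELS:
            raise ValueError(f"unknown label {label!r}; expected one of {_LABELS}")
    pred_pos = predictions == "malignant"
    true_pos = truths == "malignant"
    return ConfusionMatrix(
        tp=int((pred_pos & true_pos).sum()),
        fn=int((~pred_pos & true_pos).sum()),
        fp=int((pred_pos & ~true_pos).sum()),
        tn=int((~pred_pos & ~true_pos).sum()),
    )


def confusion_from_rates(
    sen_pct: float,
    spec_pct: float,
    n_pos: int,
    n_neg: int,
    atol_pct: float = 0.05,
) -> tuple[ConfusionMatrix, bool]:
    """Reconstruct a confusion matrix from printed SEN/SPEC and class sizes.

    Returns the matrix and a consistency flag: False when a printed rate is
    more than ``atol_pct`` percentage points away from any achievable
    count/denominator ratio, i.e. the printed value cannot have come from
    these class sizes.
    """
    if not (0 <= sen_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("rates must be percentages in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = int(round(sen_pct * n_pos / 100.0))
    tn = int(round(spec_pct * n_neg / 100.0))
    consistent = (
        abs(sen_pct - 100.0 * tp / n_pos) <= atol_pct
        and abs(spec_pct - 100.0 * tn / n_neg) <= atol_pct
    )
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn), consistent


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence bounds, in percent, via beta quantiles."""
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    upper = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return 100.0 * float(lower), 100.0 * float(upper)


def hanley_mcneil_se(auroc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUROC estimate."""
    q1 = auroc / (2.0 - auroc)
    q2 = 2.0 * auroc**2 / (1.0 + auroc)
    var = (
        auroc * (1.0 - auroc)
        + (n_pos - 1) * (q1 - auroc**2)
        + (n_neg - 1) * (q2 - auroc**2)
    ) / (n_pos * n_neg)
    # tiny negative values can arise from float cancellation at auroc ~ 1
    return math.sqrt(max(var, 0.0))


def _rate_estimate(successes: int, n: int, level: float) -> MetricEstimate:
    lower, upper = clopper_pearson(successes, n, level)
    return MetricEstimate(100.0 * successes / n, lower, upper)


def performance(cm: ConfusionMatrix, ci_level: float = 0.95) -> PerformanceReport:
    """Full diagnostic-performance report from a confusion matrix."""
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("both classes must be present to evaluate performance")
    sen = _rate_estimate(cm.tp, cm.n_pos, ci_level)
    spec = _rate_estimate(cm.tn, cm.n_neg, ci_level)
    fnr = _rate_estimate(cm.fn, cm.n_pos, ci_level)
    fpr = _rate_estimate(cm.fp, cm.n_neg, ci_level)
    ppv = _rate_estimate(cm.tp, cm.tp + cm.fp, ci_level) if cm.tp + cm.fp else None
    npv = _rate_estimate(cm.tn, cm.tn + cm.fn, ci_level) if cm.tn + cm.fn else None

    auroc_value = (sen.value / 100.0 + spec.value / 100.0) / 2.0
    se = hanley_mcneil_se(auroc_value, cm.n_pos, cm.n_neg)
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    auroc = MetricEstimate(
        auroc_value,
        max(0.0, auroc_value - z * se),
        min(1.0, auroc_value + z * se),
    )
    return PerformanceReport(
        sen=sen,
        spec=spec,
        ppv=ppv,
        npv=npv,
        fnr=fnr,
        fpr=fpr,
        auroc=auroc,
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
        ci_level=ci_level,
    )


def mcnemar(
    b_discordant: int, c_discordant: int, method: str = "exact"
) -> TestResult:
    """McNemar test from the two discordant-pair counts.

    ``exact``: two-sided binomial, p = min(1, 2 P(X <= min(b, c))) with
    X ~ Binomial(b + c, 1/2). ``chi2_cc``: continuity-corrected
    (|b - c| - 1)^2 / (b + c) on 1 df.
    """
    b, c = b_discordant, c_discordant
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method=f"mcnemar_{method}",
            note="no discordant pairs",
        )
    if method == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return TestResult(statistic=float(k), p_value=p, method="mcnemar_exact")
    if method == "chi2_cc":
        statistic = (abs(b - c) - 1) ** 2 / n
        p = float(stats.chi2.sf(statistic, df=1))
        return TestResult(statistic=statistic, p_value=p, df=1, method="mcnemar_chi2_cc")
    raise ValueError(f"unknown method {method!r}; expected 'exact' or 'chi2_cc'")


def cochran_q(indicator_matrix: np.ndarray) -> TestResult:
    """Cochran's Q for k >= 2 correlated binary classifiers (subjects x k)."""
    x = np.asarray(indicator_matrix)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D subjects x k matrix with k >= 2")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be binary")
    # rows with all-equal outcomes contribute nothing to Q; dropping them
    # also avoids a 0/0 when every subject is concordant
    informative = x[(x.min(axis=1) != x.max(axis=1))]
    if informative.shape[0] == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, df=x.shape[1] - 1, method="cochran_q",
            note="no discordant subjects",
        )
    result = sm_tables.cochrans_q(informative, return_object=True)
    return TestResult(
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        df=x.shape[1] - 1,
        method="cochran_q",
    )


def auroc_z_test(
    auroc1: float,
    n_pos1: int,
    n_neg1: int,
    auroc2: float,
    n_pos2: int,
    n_neg2: int,
) -> TestResult:
    """Two-sided z-test comparing two AUROCs via Hanley-McNeil errors.

    Treats the two estimates as independent; correlation from evaluating
    both tests on the same nodules is not accounted for.
    """
    if min(n_pos1, n_neg1, n_pos2, n_neg2) <= 0:
        raise ValueError("class sizes must be positive")
    se1 = hanley_mcneil_se(auroc1, n_pos1, n_neg1)
    se2 = hanley_mcneil_se(auroc2, n_pos2, n_neg2)
    se = math.hypot(se1, se2)
    if se == 0.0:
        if auroc1 == auroc2:
            return TestResult(statistic=0.0, p_value=1.0, method="auroc_z_unpaired")
        raise ValueError("zero standard error with unequal AUROCs")
    z = (auroc1 - auroc2) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(statistic=z, p_value=p, method="auroc_z_unpaired")


def cohens_kappa(
    ratings_a: Sequence,
    ratings_b: Sequence,
    categories: Sequence | None = None,
) -> tuple[float, float]:
    """Unweighted Cohen's kappa and the raw proportion of agreement.

    When both raters are constant and identical, chance agreement is 1 and
    kappa is undefined: returns (nan, 1.0).
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError("rating vectors differ in length")
    if not a:
        raise ValueError("rating vectors are empty")
    p_o = sum(x == y for x, y in zip(a, b)) / len(a)
    if len(set(a)) == 1 and set(a) == set(b):
        return float("nan"), p_o
    labels = list(categories) if categories is not None else None
    kappa = float(cohen_kappa_score(a, b, labels=labels))
    return kappa, p_o


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired-samples t-test on first-minus-second differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    diff = x - y
    if np.ptp(diff) == 0:
        if diff[0] != 0:
            raise ValueError("zero-variance nonzero differences: t is undefined")
        return TestResult(statistic=0.0, p_value=1.0, df=len(x) - 1, method="paired_t")
    result = stats.ttest_rel(x, y)
    return TestResult(
        statistic=float(result.statistic),
        p_value=float(result.pvalue),
        df=len(x) - 1,
        method="paired_t",
    )


def proportion_chi_square(
    table: np.ndarray | None = None,
    *,
    k: int | None = None,
    n: int | None = None,
    p0: float = 0.5,
) -> TestResult:
    """Pearson chi-square on a contingency table, or one-sample on k/n vs p0.

    The one-sample variant tests an observed proportion (e.g. the fraction
    of benign nodules with RVI > 1) against ``p0`` (default 0.5, i.e. no
    predominance of either vascularity pattern).
    """
    if table is not None:
        table = np.asarray(table, dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("contingency table has a zero marginal")
        statistic, p, df, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(
            statistic=float(statistic), p_value=float(p), df=int(df),
            method="chi2_contingency",
        )
    if k is None or n is None:
        raise ValueError("supply either a table or one-sample counts k and n")
    if not 0 <= k <= n or n == 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got {k}/{n}")
    observed = np.array([k, n - k], dtype=float)
    expected = np.array([n * p0, n * (1 - p0)])
    statistic, p = stats.chisquare(observed, expected)
    return TestResult(
        statistic=float(statistic), p_value=float(p), df=1, method="chi2_one_sample"
    )
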