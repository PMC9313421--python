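"""Diagnostic statistics against closed-form and enumeration oracles."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from thyrovasc.diagnostics import (
    ConfusionMatrix,
    auroc_z_test,
    clopper_pearson,
    cochran_q,
    cohens_kappa,
    confusion_from_rates,
    confusion_matrix,
    hanley_mcneil_se,
    mcnemar,
    paired_t_test,
    performance,
    proportion_chi_square,
    round_half_away,
)


def test_confusion_matrix_tally():
    cm = confusion_matrix(["malignant"] * 10 + ["benign"] * 10,
                          ["malignant"] * 10 + ["benign"] * 10)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (10, 0, 0, 10)
    flipped = confusion_matrix(["benign"] * 10 + ["malignant"] * 10,
                               ["malignant"] * 10 + ["benign"] * 10)
    assert (flipped.tp, flipped.tn) == (0, 0)
    assert (flipped.fn, flipped.fp) == (10, 10)


def test_confusion_matrix_matches_hand_tally_on_random_draws():
    rng = np.random.default_rng(0)
    truths = np.where(rng.random(200) < 0.3, "malignant", "benign")
    preds = np.where(rng.random(200) < 0.5, "malignant", "benign")
    cm = confusion_matrix(preds, truths)
    hand = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for p, t in zip(preds, truths):
        key = ("t" if p == t else "f") + ("p" if p == "malignant" else "n")
        hand[key] += 1
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (hand["tp"], hand["fn"], hand["fp"], hand["tn"])


def test_confusion_matrix_rejects_unknown_labels():
    with pytest.raises(ValueError, match="unknown label"):
        confusion_matrix(["positive"], ["malignant"])


@pytest.mark.parametrize(
    "sen,spec,n_pos,n_neg,expected",
    [
        (83.3, 50.0, 30, 64, (25, 5, 32, 32)),
        (100.0, 100.0, 9, 31, (9, 0, 0, 31)),
        (66.7, 73.4, 30, 64, (20, 10, 17, 47)),
    ],
)
def test_confusion_from_rates(sen, spec, n_pos, n_neg, expected):
    cm, consistent = confusion_from_rates(sen, spec, n_pos, n_neg)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == expected
    assert consistent


def test_confusion_from_rates_flags_impossible_rate():
    # 58.1% of 30 is not achievable by any integer count
    _, consistent = confusion_from_rates(58.1, 81.3, 30, 64)
    assert not consistent


@pytest.mark.parametrize(
    "counts,ppv,npv,auroc",
    [
        ((25, 5, 32, 32), 43.9, 86.5, 0.67),
        ((23, 7, 10, 54), 69.7, 88.5, 0.81),
    ],
)
def test_performance_worked_examples(counts, ppv, npv, auroc):
    report = performance(ConfusionMatrix(*counts))
    assert round_half_away(report.ppv.value, 1) == ppv
    assert round_half_away(report.npv.value, 1) == npv
    assert round_half_away(report.auroc.value, 2) == auroc


def test_performance_perfect_classifier():
    report = performance(ConfusionMatrix(10, 0, 0, 20))
    assert report.sen.value == report.spec.value == 100.0
    assert report.ppv.value == report.npv.value == 100.0
    assert report.auroc.value == 1.0


def test_performance_identities_hold_on_random_matrices():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tp, fn, fp, tn = rng.integers(0, 40, 4)
        if tp + fn == 0 or fp + tn == 0:
            continue
        r = performance(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
        assert r.fnr.value == pytest.approx(100 - r.sen.value)
        assert r.fpr.value == pytest.approx(100 - r.spec.value)
        assert r.auroc.value == pytest.approx((r.sen.value + r.spec.value) / 200)
        for est in (r.sen, r.spec, r.fnr, r.fpr, r.auroc):
            assert est.ci_lower <= est.value <= est.ci_upper


def test_performance_undefined_predictive_values():
    report = performance(ConfusionMatrix(tp=0, fn=5, fp=0, tn=5))
    assert report.ppv is None  # no positive calls
    assert report.npv is not None


@pytest.mark.parametrize(
    "successes,n,expected",
    [(25, 30, (65.3, 94.4)), (8, 9, (51.8, 99.7))],
)
def test_clopper_pearson_printed_bounds(successes, n, expected):
    lower, upper = clopper_pearson(successes, n, 0.95)
    assert (round_half_away(lower, 1), round_half_away(upper, 1)) == expected


def test_clopper_pearson_boundaries():
    lower, upper = clopper_pearson(0, 20, 0.95)
    assert lower == 0.0 and upper < 100
    lower, upper = clopper_pearson(20, 20, 0.95)
    assert upper == 100.0 and lower > 0
    with pytest.raises(ValueError):
        clopper_pearson(5, 3, 0.95)


def test_mcnemar_symmetric_and_empty():
    assert mcnemar(5, 5).p_value == 1.0
    empty = mcnemar(0, 0)
    assert empty.p_value == 1.0 and empty.note == "no discordant pairs"


def test_mcnemar_exact_brute_force_value():
    # sum_{k<=2} C(12,k)/2^12, doubled
    assert mcnemar(10, 2).p_value == pytest.approx(2 * 79 / 4096)


def test_mcnemar_exact_equals_enumeration_for_all_small_tables():
    for n in range(1, 21):
        for b in range(n + 1):
            c = n - b
            k = min(b, c)
            expected = min(1.0, 2 * sum(math.comb(n, i) for i in range(k + 1)) / 2**n)
            assert mcnemar(b, c).p_value == pytest.approx(expected)


def test_mcnemar_exact_agrees_with_statsmodels():
    for b, c in [(10, 2), (3, 8), (0, 7), (6, 6)]:
        table = [[0, b], [c, 0]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar(b, c).p_value == pytest.approx(expected)


def test_mcnemar_chi2_cc():
    result = mcnemar(10, 2, method="chi2_cc")
    assert result.statistic == pytest.approx((abs(10 - 2) - 1) ** 2 / 12)
    assert result.p_value == pytest.approx(stats.chi2.sf(result.statistic, 1))


def test_cochran_q_identical_columns():
    x = np.tile(np.array([1, 0, 1, 1, 0])[:, None], (1, 3))
    result = cochran_q(x)
    assert result.statistic == 0.0 and result.p_value == 1.0


def test_cochran_q_k2_equals_uncorrected_mcnemar_chi2():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 2, (30, 2))
    b = int(((x[:, 0] == 1) & (x[:, 1] == 0)).sum())
    c = int(((x[:, 0] == 0) & (x[:, 1] == 1)).sum())
    assert cochran_q(x).statistic == pytest.approx((b - c) ** 2 / (b + c))


def test_cochran_q_matches_formula_oracle():
    x = np.array(
        [[1, 1, 0], [1, 0, 0], [0, 1, 1], [1, 1, 1], [0, 0, 0], [1, 0, 1]]
    )
    k = x.shape[1]
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    n_total = x.sum()
    q = (k - 1) * (k * (col**2).sum() - n_total**2) / (k * n_total - (row**2).sum())
    result = cochran_q(x)
    assert result.statistic == pytest.approx(q)
    assert result.p_value == pytest.approx(stats.chi2.sf(q, k - 1))
    with pytest.raises(ValueError):
        cochran_q(x[:, :1])


def test_auroc_z_test_trivial_and_oracle():
    assert auroc_z_test(0.8, 30, 64, 0.8, 30, 64).p_value == 1.0
    assert hanley_mcneil_se(1.0, 30, 64) == 0.0
    a1, a2 = 0.81, 0.67
    se1 = hanley_mcneil_se(a1, 30, 64)
    se2 = hanley_mcneil_se(a2, 30, 64)
    # independent re-derivation of the variance formula
    def hm_var(a, n1, n2):
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        return (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
    assert se1**2 == pytest.approx(hm_var(a1, 30, 64))
    result = auroc_z_test(a1, 30, 64, a2, 30, 64)
    expected_z = (a1 - a2) / math.sqrt(hm_var(a1, 30, 64) + hm_var(a2, 30, 64))
    assert result.statistic == pytest.approx(expected_z)
    assert result.p_value == pytest.approx(2 * stats.norm.sf(abs(expected_z)))


def test_cohens_kappa_cases():
    grades = ["I", "II", "III", "IV"] * 5
    kappa, agreement = cohens_kappa(grades, grades)
    assert kappa == 1.0 and agreement == 1.0
    # independent ratings: observed agreement equals chance agreement
    a = ["I", "I", "II", "II"]
    b = ["I", "II", "I", "II"]
    kappa, agreement = cohens_kappa(a, b)
    assert kappa == pytest.approx(0.0)
    assert agreement == 0.5
    kappa, agreement = cohens_kappa(["I"] * 4, ["I"] * 4)
    assert math.isnan(kappa) and agreement == 1.0


def test_cohens_kappa_matches_hand_formula():
    rng = np.random.default_rng(9)
    cats = ["I", "II", "III", "IV"]
    a = rng.choice(cats, 80).tolist()
    b = rng.choice(cats, 80).tolist()
    kappa, p_o = cohens_kappa(a, b, categories=cats)
    p_e = sum((a.count(c) / 80) * (b.count(c) / 80) for c in cats)
    assert p_o == sum(x == y for x, y in zip(a, b)) / 80
    assert kappa == pytest.approx((p_o - p_e) / (1 - p_e))


def test_paired_t_identical_samples():
    result = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert result.statistic == 0.0 and result.p_value == 1.0


def test_paired_t_closed_form_and_direction():
    x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
    y = np.array([13.0, 15.0, 10.0, 18.0, 12.0])
    diff = x - y
    expected_t = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
    result = paired_t_test(x, y)
    assert result.statistic == pytest.approx(expected_t)
    assert result.df == 4
    # first-minus-second convention: lower first sample gives negative t
    rng = np.random.default_rng(4)
    first = rng.normal(40, 10, 94)
    second = first + 10 + rng.normal(0, 10, 94)
    shifted = paired_t_test(first, second)
    assert shifted.statistic < -5
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t_test([1.0, 2.0], [2.0, 3.0])


def test_chi_square_contingency_and_one_sample():
    same_rows = np.array([[10, 20], [10, 20]])
    result = proportion_chi_square(same_rows)
    assert result.statistic == pytest.approx(0.0) and result.p_value == pytest.approx(1.0)
    # all n of n successes against p0 = 0.5 gives statistic n
    result = proportion_chi_square(k=24, n=24, p0=0.5)
    assert result.statistic == pytest.approx(24)
    table = np.array([[12, 5], [7, 16]])
    expected = stats.chi2_contingency(table, correction=False)[0]
    assert proportion_chi_square(table).statistic == pytest.approx(expected)
    with pytest.raises(ValueError, match="marginal"):
        proportion_chi_square(np.array([[0, 0], [1, 2]]))


def test_round_half_away():
    assert round_half_away(56.25, 1) == 56.3
    assert round_half_away(0.815, 2) == 0.82
    assert round_half_away(-2.5, 0) == -3.0
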