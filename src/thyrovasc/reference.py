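"""Published operating points of the reference thyroid-nodule cohort.

The study cohort behind this package (94 nodules: 30 malignant, 64 benign;
40 with equivocal cytology: 9 malignant, 31 benign) is not publicly
available, but the published per-assessment sensitivity and specificity,
together with the class sizes, determine the full confusion matrix of each
binary assessment. PPV, NPV and the single-operating-point AUROC are then
deterministic functions of that matrix, so every published cell can be
recomputed and checked for internal consistency.

``check_reference_consistency`` reconstructs each assessment's confusion
matrix from its published SEN/SPEC, re-derives PPV/NPV/AUROC with
:func:`thyrovasc.diagnostics.performance`, and compares against the
published values at their printed precision (one decimal for percentages,
two for AUROC). Cells that cannot be reproduced from the stated class
sizes are flagged rather than silently accepted.
"""

from __future__ import annotations

import pandas as pd

from .diagnostics import confusion_from_rates, performance, round_half_away

__all__ = [
    "COHORT_SIZES",
    "reference_operating_points",
    "check_reference_consistency",
]

#: (n_malignant, n_benign) for the full cohort and the equivocal subset.
COHORT_SIZES = {"all": (30, 64), "equivocal": (9, 31)}

# assessment, subset, published SEN %, SPEC %, PPV %, NPV %, AUROC
_OPERATING_POINTS = [
    ("eu_tirads", "all", 83.3, 50.0, 43.9, 86.5, 0.67),
    ("eu_tirads", "equivocal", 88.9, 38.7, 29.6, 92.3, 0.62),
    ("qual_cfi", "all", 53.3, 92.2, 76.2, 80.8, 0.73),
    ("qual_acfi", "all", 80.0, 82.8, 68.6, 89.8, 0.81),
    ("qual_pdi", "all", 46.7, 95.3, 82.4, 79.2, 0.71),
    ("qual_apdi", "all", 83.3, 81.3, 67.6, 91.2, 0.82),
    ("qual_cfi", "equivocal", 66.7, 90.3, 66.7, 90.3, 0.79),
    ("qual_acfi", "equivocal", 88.9, 80.6, 57.1, 96.2, 0.85),
    ("qual_pdi", "equivocal", 66.7, 93.5, 75.0, 90.6, 0.80),
    ("qual_apdi", "equivocal", 100.0, 77.4, 56.3, 100.0, 0.89),
    ("rvi_cfi", "all", 56.7, 81.3, 58.6, 80.0, 0.69),
    ("rvi_acfi", "all", 60.0, 73.4, 51.4, 79.7, 0.67),
    ("rvi_pdi", "all", 46.7, 65.6, 38.9, 72.4, 0.56),
    ("rvi_apdi", "all", 66.7, 73.4, 54.1, 82.5, 0.70),
    ("rvi_cfi", "equivocal", 66.7, 83.9, 54.5, 89.7, 0.75),
    ("rvi_acfi", "equivocal", 55.6, 67.7, 33.3, 84.0, 0.62),
    ("rvi_pdi", "equivocal", 33.3, 61.3, 20.0, 76.0, 0.47),
    ("rvi_apdi", "equivocal", 77.8, 74.2, 46.7, 92.0, 0.76),
    ("eu_plus_apdi_qual", "all", 76.7, 84.4, 69.7, 88.5, 0.81),
    ("eu_plus_apdi_rvi", "all", 58.1, 81.0, 60.0, 79.7, 0.70),
    ("eu_plus_apdi_qual", "equivocal", 88.9, 77.4, 53.3, 96.0, 0.83),
    ("eu_plus_apdi_rvi", "equivocal", 66.7, 74.2, 42.9, 88.5, 0.70),
]


def reference_operating_points() -> pd.DataFrame:
    """Published SEN/SPEC/PPV/NPV/AUROC per assessment and cohort subset."""
    return pd.DataFrame(
        _OPERATING_POINTS,
        columns=["assessment", "subset", "sen", "spec", "ppv", "npv", "auroc"],
    )


def check_reference_consistency(ci_level: float = 0.95) -> pd.DataFrame:
    """Recompute every published PPV/NPV/AUROC cell from SEN/SPEC + class sizes.

    Returns one row per assessment x subset with the reconstructed counts,
    the recomputed metrics rounded at printed precision, and boolean
    ``*_consistent`` flags. ``rates_consistent`` is False when the
    published SEN or SPEC itself cannot arise from the stated class sizes
    (in which case the derived cells are not comparable either).
    """
    rows = []
    for assessment, subset, sen, spec, ppv, npv, auroc in _OPERATING_POINTS:
        n_pos, n_neg = COHORT_SIZES[subset]
        cm, rates_ok = confusion_from_rates(sen, spec, n_pos, n_neg)
        report = performance(cm, ci_level=ci_level)
        ppv_rc = round_half_away(report.ppv.value, 1)
        npv_rc = round_half_away(report.npv.value, 1)
        auroc_rc = round_half_away(report.auroc.value, 2)
        rows.append(
            {
                "assessment": assessment,
                "subset": subset,
                "n_pos": n_pos,
                "n_neg": n_neg,
                "tp": cm.tp,
                "fn": cm.fn,
                "fp": cm.fp,
                "tn": cm.tn,
                "sen_published": sen,
                "spec_published": spec,
                "rates_consistent": rates_ok,
                "ppv_published": ppv,
                "ppv_recomputed": ppv_rc,
                "ppv_consistent": rates_ok and ppv_rc == ppv,
                "npv_published": npv,
                "npv_recomputed": npv_rc,
                "npv_consistent": rates_ok and npv_rc == npv,
                "auroc_published": auroc,
                "auroc_recomputed": auroc_rc,
                "auroc_consistent": rates_ok and auroc_rc == auroc,
            }
        )
    return pd.DataFrame(rows)
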