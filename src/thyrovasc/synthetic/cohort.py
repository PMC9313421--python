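"""Simulated nodule cohorts with the reference study's label structure.

The default specification reproduces the study conditions: 94 nodules
(30 malignant, 64 benign) of which 40 are cytologically equivocal
(9 malignant, 31 benign), three replicate acquisitions per nodule per
Doppler mode, and per-mode operating points for the two suspicion
indicators — qualitative grading and the RVI rule — taken from the
published all-nodule sensitivities and specificities.

For each nodule and mode, the qualitative and quantitative
malignancy-suspicion indicators are drawn Bernoulli(SEN) for malignant and
Bernoulli(1 - SPEC) for benign nodules. Indicators are independent across
modes given truth by default; a shared-latent Gaussian-copula correlation
is available. The qualitative grade is then drawn within the indicated
half of the scale (I/II for benign-leaning, III/IV for malignancy-leaning),
and the replicate (peripheral, central) VI pairs are drawn around
nodule-level means whose ratio matches the quantitative indicator, with
Gaussian replicate jitter (default sd 3 VI points) truncated to [0, 100].
Replicate jitter is redrawn, deterministically, in the rare case where it
would flip the replicate-mean RVI against the nodule's indicator, so the
emitted table is internally consistent. The equivocal flag is assigned
independently of the indicators given truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ..vascularity import DOPPLER_MODES

__all__ = ["CohortSpec", "generate_cohort"]

# all-nodule operating points of the qualitative grading (fractions)
_QUAL_SEN = {"CFI": 0.533, "ACFI": 0.800, "PDI": 0.467, "APDI": 0.833}
_QUAL_SPEC = {"CFI": 0.922, "ACFI": 0.828, "PDI": 0.953, "APDI": 0.813}
# all-nodule operating points of the RVI rule (fractions)
_RVI_SEN = {"CFI": 0.567, "ACFI": 0.600, "PDI": 0.467, "APDI": 0.667}
_RVI_SPEC = {"CFI": 0.813, "ACFI": 0.734, "PDI": 0.656, "APDI": 0.734}

# per-truth EU TIRADS category distributions chosen so that, marginally,
# P(cat 5) matches the sole grey-scale operating point (0.833 / 0.500) and
# P(cat >= 4) matches the combined-assessment operating point under the
# AND rule with the qualitative APDI indicator (0.921 / 0.834)
_TIRADS_PROBS = {
    "malignant": {2: 0.029, 3: 0.050, 4: 0.088, 5: 0.833},
    "benign": {2: 0.046, 3: 0.120, 4: 0.334, 5: 0.500},
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort simulation parameters; defaults are the study conditions."""

    n_total: int = 94
    n_malignant: int = 30
    n_equivocal_malignant: int = 9
    n_equivocal_benign: int = 31
    qual_sensitivity: dict = field(default_factory=lambda: dict(_QUAL_SEN))
    qual_specificity: dict = field(default_factory=lambda: dict(_QUAL_SPEC))
    rvi_sensitivity: dict = field(default_factory=lambda: dict(_RVI_SEN))
    rvi_specificity: dict = field(default_factory=lambda: dict(_RVI_SPEC))
    tirads_category_probs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _TIRADS_PROBS.items()}
    )
    n_replicates: int = 3
    replicate_jitter_sd: float = 3.0
    mode_correlation: float = 0.0  # shared-latent copula rho across modes
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_malignant <= self.n_total:
            raise ValueError("need 0 < n_malignant <= n_total")
        n_benign = self.n_total - self.n_malignant
        if self.n_equivocal_malignant > self.n_malignant:
            raise ValueError("more equivocal malignant nodules than malignant nodules")
        if self.n_equivocal_benign > n_benign:
            raise ValueError("more equivocal benign nodules than benign nodules")
        for table in (
            self.qual_sensitivity, self.qual_specificity,
            self.rvi_sensitivity, self.rvi_specificity,
        ):
            for mode in DOPPLER_MODES:
                p = table[mode]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of range for {mode}: {p}")
        for truth, probs in self.tirads_category_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"category probabilities for {truth!r} sum to {total}, not 1"
                )
        if not 0.0 <= self.mode_correlation < 1.0:
            raise ValueError("mode_correlation must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _correlated_bernoulli(
    p: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """n x k binary draws with marginals p (n x k) and copula correlation rho."""
    n, k = p.shape
    if rho == 0.0:
        return (rng.random((n, k)) < p).astype(np.int8)
    shared = rng.standard_normal((n, 1))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
    return (stats.norm.cdf(z) < p).astype(np.int8)


def _vi_means(
    central_predominant: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Nodule-level (peripheral, central) VI means matching each indicator.

    The smaller regional VI is uniform on [8, 35] and the larger one
    exceeds it by a ratio in [1.3, 3] (capped at 95), leaving enough margin
    that replicate jitter rarely flips the RVI classification.
    """
    n = central_predominant.shape
    low = rng.uniform(8.0, 35.0, n)
    ratio = rng.uniform(1.3, 3.0, n)
    high = np.minimum(low * ratio, 95.0)
    vi_p = np.where(central_predominant == 1, low, high)
    vi_c = np.where(central_predominant == 1, high, low)
    return vi_p, vi_c


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table, one row per nodule.

    Columns: ``nodule_id``, ``truth``, ``equivocal``, ``tirads_category``,
    per-mode qualitative grades ``grade_<mode>`` and replicate VI columns
    ``vi_p_<mode>_<r>`` / ``vi_c_<mode>_<r>`` (r = 1..n_replicates, mode
    names lower-case). Identical spec (including seed) gives an identical
    table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    n_mal = spec.n_malignant
    n_ben = n - n_mal
    malignant = np.zeros(n, dtype=bool)
    malignant[:n_mal] = True

    equivocal = np.zeros(n, dtype=bool)
    equivocal[rng.choice(n_mal, spec.n_equivocal_malignant, replace=False)] = True
    equivocal[n_mal + rng.choice(n_ben, spec.n_equivocal_benign, replace=False)] = True

    categories = np.empty(n, dtype=int)
    for truth, mask in (("malignant", malignant), ("benign", ~malignant)):
        probs = spec.tirads_category_probs[truth]
        cats = np.array(sorted(probs))
        weights = np.array([probs[c] for c in cats], dtype=float)
        categories[mask] = rng.choice(cats, size=int(mask.sum()), p=weights / weights.sum())

    def indicator_block(sen: dict, specificity: dict) -> np.ndarray:
        p = np.empty((n, len(DOPPLER_MODES)))
        for j, mode in enumerate(DOPPLER_MODES):
            p[:, j] = np.where(malignant, sen[mode], 1.0 - specificity[mode])
        return _correlated_bernoulli(p, spec.mode_correlation, rng)

    qual_suspicious = indicator_block(spec.qual_sensitivity, spec.qual_specificity)
    rvi_suspicious = indicator_block(spec.rvi_sensitivity, spec.rvi_specificity)

    data: dict[str, object] = {
        "nodule_id": [f"n{i:05d}" for i in range(n)],
        "truth": np.where(malignant, "malignant", "benign"),
        "equivocal": equivocal,
        "tirads_category": categories,
    }

    grade_pool = {0: np.array(["I", "II"]), 1: np.array(["III", "IV"])}
    for j, mode in enumerate(DOPPLER_MODES):
        pick = rng.integers(0, 2, n)
        suspicious = qual_suspicious[:, j]
        grades = np.where(
            suspicious == 1, grade_pool[1][pick], grade_pool[0][pick]
        )
        data[f"grade_{mode.lower()}"] = grades

    n_rep = spec.n_replicates
    for j, mode in enumerate(DOPPLER_MODES):
        central_pred = rvi_suspicious[:, j]
        mean_p, mean_c = _vi_means(central_pred, rng)
        rep_p = np.clip(
            mean_p[:, None] + rng.normal(0, spec.replicate_jitter_sd, (n, n_rep)),
            0.0, 100.0,
        )
        rep_c = np.clip(
            mean_c[:, None] + rng.normal(0, spec.replicate_jitter_sd, (n, n_rep)),
            0.0, 100.0,
        )
        # redraw jitter where the replicate-mean RVI disagrees with the
        # indicator (RVI <= 1 must hold iff central-predominant)
        for _ in range(100):
            realised_central = rep_p.mean(axis=1) <= rep_c.mean(axis=1)
            bad = realised_central != (central_pred == 1)
            if not bad.any():
                break
            k = int(bad.sum())
            rep_p[bad] = np.clip(
                mean_p[bad, None] + rng.normal(0, spec.replicate_jitter_sd, (k, n_rep)),
                0.0, 100.0,
            )
            rep_c[bad] = np.clip(
                mean_c[bad, None] + rng.normal(0, spec.replicate_jitter_sd, (k, n_rep)),
                0.0, 100.0,
            )
        else:
            raise RuntimeError("could not reconcile replicate jitter with indicators")
        for r in range(n_rep):
            data[f"vi_p_{mode.lower()}_{r + 1}"] = rep_p[:, r]
            data[f"vi_c_{mode.lower()}_{r + 1}"] = rep_c[:, r]

    return pd.DataFrame(data)
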