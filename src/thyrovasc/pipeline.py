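"""End-to-end orchestration: quantify images, evaluate cohorts, compare tests.

``run_quantify`` turns a directory of Doppler frames plus ROI masks into
per-replicate and per-nodule vascularity tables. ``run_evaluate`` scores
every assessment (sole grey-scale EU TIRADS, qualitative grading and the
RVI rule per Doppler mode, and the two EU TIRADS + APDI combinations) on
the full cohort and on the cytologically-equivocal subset. ``run_compare``
runs the paired McNemar tests on sensitivity and specificity, Cochran's Q
across the four modes, and z-tests between AUROCs.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import diagnostics, tirads, vascularity
from .config import RunConfig
from .segmentation import partition_regions, region_areas
from .vascularity import DOPPLER_MODES, MALIGNANT_SUSPICIOUS, NON_VASCULAR

__all__ = ["run_quantify", "run_evaluate", "run_compare", "QUANTIFY_STEM"]

logger = logging.getLogger(__name__)

#: filename convention linking a frame to its nodule, mode and replicate
QUANTIFY_STEM = re.compile(
    r"^(?P<nodule>.+)_(?P<mode>cfi|acfi|pdi|apdi)_(?P<replicate>\d+)$", re.IGNORECASE
)


def _parse_stem(stem: str) -> tuple[str, str | None, int]:
    match = QUANTIFY_STEM.match(stem)
    if match:
        return (
            match["nodule"],
            match["mode"].upper(),
            int(match["replicate"]),
        )
    return stem, None, 1


def run_quantify(
    image_dir: str | Path,
    mask_dir: str | Path,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Quantify regional vascularity for every image in a directory.

    Each ``<stem>.png`` in ``image_dir`` needs a ``<stem>_mask.png`` (or
    ``<stem>.png``) mask in ``mask_dir``. Returns (per-replicate table,
    per-nodule aggregated table, list of per-file failure messages). Files
    that fail are reported and skipped; the run continues. Aggregated rows
    that are non-vascular (both mean VIs zero) are excluded with a logged
    count.
    """
    config = config or RunConfig()
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir)
    images = sorted(image_dir.glob("*.png"))
    if not images:
        raise FileNotFoundError(f"no images found in {image_dir}")

    rows = []
    failures: list[str] = []
    for image_path in images:
        stem = image_path.stem
        mask_path = mask_dir / f"{stem}_mask.png"
        if not mask_path.exists():
            mask_path = mask_dir / image_path.name
        if not mask_path.exists():
            failures.append(f"{image_path.name}: no matching mask")
            continue
        try:
            image = np.asarray(iio.imread(image_path))
            mask = np.asarray(iio.imread(mask_path)) > 0
            if mask.ndim == 3:
                mask = mask[..., 0]
            if mask.shape != image.shape[:2]:
                raise ValueError(
                    f"mask shape {mask.shape} does not match image {image.shape[:2]}"
                )
            part = partition_regions(mask, config.offset_fraction)
            vi_p, vi_c, vi_overall = vascularity.measure_regions(
                image, part, config.chroma_threshold
            )
        except Exception as exc:  # per-file isolation, run continues
            failures.append(f"{image_path.name}: {exc}")
            continue
        nodule, mode, replicate = _parse_stem(stem)
        area_c, area_p = region_areas(part)
        rows.append(
            {
                "nodule_id": nodule,
                "mode": mode,
                "replicate": replicate,
                "vi_p": vi_p,
                "vi_c": vi_c,
                "vi_overall": vi_overall,
                "area_peripheral": area_p,
                "area_central": area_c,
            }
        )
    for message in failures:
        logger.warning("quantify failure: %s", message)
    per_replicate = pd.DataFrame(rows)
    if per_replicate.empty:
        return per_replicate, per_replicate, failures

    aggregated_rows = []
    n_non_vascular = 0
    for (nodule, mode), group in per_replicate.groupby(["nodule_id", "mode"], dropna=False):
        m = vascularity.aggregate_replicates(
            list(zip(group["vi_p"], group["vi_c"])),
            mode=mode,
            area_peripheral=int(group["area_peripheral"].iloc[0]),
            area_central=int(group["area_central"].iloc[0]),
        )
        if m.suspicion == NON_VASCULAR:
            n_non_vascular += 1
            continue
        aggregated_rows.append(
            {
                "nodule_id": nodule,
                "mode": mode,
                "n_replicates": m.n_replicates,
                "vi_p": m.vi_peripheral,
                "vi_c": m.vi_central,
                "vi_overall": m.vi_overall,
                "rvi": m.rvi,
                "suspicion": m.suspicion,
            }
        )
    if n_non_vascular:
        logger.info("excluded %d non-vascular nodule measurements", n_non_vascular)
    return per_replicate, pd.DataFrame(aggregated_rows), failures


def _replicate_columns(cohort: pd.DataFrame, mode: str, prefix: str) -> list[str]:
    pattern = re.compile(rf"^{prefix}_{mode.lower()}_\d+$")
    return [c for c in cohort.columns if pattern.match(c)]


def cohort_rvi(cohort: pd.DataFrame, mode: str) -> pd.Series:
    """Replicate-mean RVI of one Doppler mode for every cohort row."""
    p_cols = _replicate_columns(cohort, mode, "vi_p")
    c_cols = _replicate_columns(cohort, mode, "vi_c")
    if not p_cols or not c_cols:
        raise KeyError(f"cohort table lacks replicate VI columns for mode {mode}")
    mean_p = cohort[p_cols].mean(axis=1)
    mean_c = cohort[c_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rvi = mean_p / mean_c
    rvi[(mean_c == 0) & (mean_p > 0)] = np.inf
    rvi[(mean_c == 0) & (mean_p == 0)] = np.nan  # non-vascular
    return rvi


def _assessment_predictions(
    cohort: pd.DataFrame, config: RunConfig
) -> dict[str, pd.Series]:
    """Boolean predicts-malignant vector per assessment (NaN rows excluded later)."""
    required = {"truth", "equivocal", "tirads_category"}
    missing = required - set(cohort.columns)
    if missing:
        raise KeyError(f"cohort table is missing required columns: {sorted(missing)}")

    predictions: dict[str, pd.Series] = {}
    categories = cohort["tirads_category"].astype(int)
    predictions["eu_tirads"] = categories.map(
        lambda c: tirads.classify_tirads(c, "sole_ge5")
    )
    tirads_ge4 = categories.map(lambda c: tirads.classify_tirads(c, "combined_ge4"))

    for mode in DOPPLER_MODES:
        grade_col = f"grade_{mode.lower()}"
        if grade_col in cohort.columns:
            predictions[f"qual_{mode.lower()}"] = cohort[grade_col].map(
                lambda g: vascularity.classify_qualitative(g) == MALIGNANT_SUSPICIOUS
            )
        try:
            rvi = cohort_rvi(cohort, mode)
        except KeyError:
            continue
        n_non_vascular = int(rvi.isna().sum())
        if n_non_vascular:
            logger.info(
                "mode %s: excluding %d non-vascular nodules from RVI assessment",
                mode, n_non_vascular,
            )
        # float encoding (1/0/NaN) so non-vascular rows stay distinguishable
        predictions[f"rvi_{mode.lower()}"] = pd.Series(
            np.where(rvi.isna(), np.nan, (rvi <= config.rvi_threshold).astype(float)),
            index=cohort.index,
        )

    if "qual_apdi" in predictions:
        predictions["eu_plus_apdi_qual"] = tirads_ge4 & predictions["qual_apdi"]
    if "rvi_apdi" in predictions:
        rvi_apdi = predictions["rvi_apdi"]
        predictions["eu_plus_apdi_rvi"] = pd.Series(
            np.where(
                rvi_apdi.isna(),
                np.nan,
                (tirads_ge4.to_numpy() & (rvi_apdi.to_numpy() == 1.0)).astype(float),
            ),
            index=cohort.index,
        )
    return predictions


def run_evaluate(cohort: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Diagnostic performance of every assessment on all and equivocal nodules.

    Returns a tidy table: one row per (assessment, subset) with SEN, SPEC,
    PPV, NPV, FNR, FPR (percent, with exact CI bounds) and AUROC (0-1,
    Hanley-McNeil CI).
    """
    config = config or RunConfig()
    predictions = _assessment_predictions(cohort, config)
    truth_malignant = cohort["truth"] == "malignant"
    subsets = {
        "all": pd.Series(True, index=cohort.index),
        "equivocal": cohort["equivocal"].astype(bool),
    }
    rows = []
    for name, predicted in predictions.items():
        valid = predicted.notna()
        predicted_bool = predicted[valid].astype(bool)
        for subset_name, in_subset in subsets.items():
            sel = in_subset & valid
            cm = diagnostics.confusion_matrix(
                np.where(predicted_bool[sel[valid]], "malignant", "benign"),
                np.where(truth_malignant[sel], "malignant", "benign"),
            )
            report = diagnostics.performance(cm, ci_level=config.ci_level)
            row = {"assessment": name, "subset": subset_name,
                   "n_pos": report.n_pos, "n_neg": report.n_neg}
            for metric in ("sen", "spec", "ppv", "npv", "fnr", "fpr", "auroc"):
                estimate = getattr(report, metric)
                if estimate is None:
                    row[metric] = row[f"{metric}_lo"] = row[f"{metric}_hi"] = np.nan
                else:
                    row[metric] = estimate.value
                    row[f"{metric}_lo"] = estimate.ci_lower
                    row[f"{metric}_hi"] = estimate.ci_upper
            rows.append(row)
    return pd.DataFrame(rows)


def _significance(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


_DEFAULT_PAIRS = [
    ("qual_cfi", "qual_acfi"),
    ("qual_pdi", "qual_apdi"),
    ("rvi_cfi", "rvi_acfi"),
    ("rvi_pdi", "rvi_apdi"),
    ("eu_tirads", "eu_plus_apdi_qual"),
    ("eu_tirads", "eu_plus_apdi_rvi"),
]


def run_compare(
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired comparisons between assessments on the same nodules.

    For each assessment pair: exact McNemar within malignant nodules
    (sensitivity) and within benign nodules (specificity), plus the AUROC
    z-test. Cochran's Q rows cover the four qualitative and the four RVI
    mode indicators within each truth class. Rows where a pair has no
    jointly valid nodules are omitted.
    """
    config = config or RunConfig()
    predictions = _assessment_predictions(cohort, config)
    truth_malignant = (cohort["truth"] == "malignant").to_numpy()
    pairs = pairs if pairs is not None else _DEFAULT_PAIRS

    rows = []
    for a, b in pairs:
        if a not in predictions or b not in predictions:
            continue
        pa, pb = predictions[a], predictions[b]
        valid = (pa.notna() & pb.notna()).to_numpy()
        xa = pa[valid].astype(bool).to_numpy()
        xb = pb[valid].astype(bool).to_numpy()
        truth_v = truth_malignant[valid]
        for metric, sel, correct_when in (
            ("sensitivity", truth_v, True),
            ("specificity", ~truth_v, False),
        ):
            ca = xa[sel] == correct_when
            cb = xb[sel] == correct_when
            result = diagnostics.mcnemar(int((ca & ~cb).sum()), int((~ca & cb).sum()))
            rows.append(
                {
                    "comparison": f"{a} vs {b}",
                    "metric": metric,
                    "method": result.method,
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "significance": _significance(result.p_value),
                }
            )
        auroc = {}
        for name, x in (("a", xa), ("b", xb)):
            cm = diagnostics.confusion_matrix(
                np.where(x, "malignant", "benign"),
                np.where(truth_v, "malignant", "benign"),
            )
            report = diagnostics.performance(cm)
            auroc[name] = (report.auroc.value, report.n_pos, report.n_neg)
        result = diagnostics.auroc_z_test(*auroc["a"], *auroc["b"])
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "metric": "auroc",
                "method": result.method,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "significance": _significance(result.p_value),
            }
        )

    for family in ("qual", "rvi"):
        names = [f"{family}_{m.lower()}" for m in DOPPLER_MODES]
        if not all(n in predictions for n in names):
            continue
        block = pd.concat([predictions[n] for n in names], axis=1)
        valid = block.notna().all(axis=1).to_numpy()
        matrix = block[valid].astype(bool).to_numpy().astype(int)
        for truth_name, sel in (
            ("malignant", truth_malignant[valid]),
            ("benign", ~truth_malignant[valid]),
        ):
            if sel.sum() == 0:
                continue
            result = diagnostics.cochran_q(matrix[sel])
            rows.append(
                {
                    "comparison": f"{family} modes ({truth_name})",
                    "metric": "indicator homogeneity",
                    "method": result.method,
                    "statistic": result.statistic,
                    "p_value": result.p_value,
                    "significance": _significance(result.p_value),
                }
            )
    return pd.DataFrame(rows)
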