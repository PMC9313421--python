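"""Colour-pixel detection, vascularity indices (VI) and the ratio index (RVI).

A Doppler ultrasound frame overlays pure colour (flow signal) on a greyscale
B-mode background. A pixel carries Doppler signal when its chroma —
``max(R, G, B) - min(R, G, B)`` — exceeds a threshold (default 10 on an
8-bit scale, tolerating mild compression noise). The vascularity index of a
region is the percentage of its pixels that carry colour:

    VI = 100 * |colour pixels in region| / |region|

Per-nodule VIs are the arithmetic means of the replicate acquisitions
(three per Doppler mode in the reference protocol), and the ratio
vascularity index is the ratio of those means:

    RVI = mean peripheral VI / mean central VI

RVI > 1 marks predominantly peripheral vascularity (suspicious for
benignity); RVI <= 1 marks predominantly central vascularity (suspicious
for malignancy). Nodules with colour in the periphery only get RVI = +inf
(benign-leaning); nodules with no colour at all are *non-vascular* and are
excluded from diagnostic evaluation, mirroring the study's exclusion
criteria.

Qualitative grading (the human assessment) uses four categories:
I exclusively peripheral, II predominantly peripheral, III predominantly
central, IV exclusively central; I/II map to benign-suspicion and III/IV to
malignancy-suspicion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BENIGN_SUSPICIOUS",
    "MALIGNANT_SUSPICIOUS",
    "NON_VASCULAR",
    "DOPPLER_MODES",
    "QUALITATIVE_GRADES",
    "VascularityMeasurement",
    "detect_colour_pixels",
    "compute_vi",
    "aggregate_replicates",
    "classify_rvi",
    "classify_qualitative",
    "measure_regions",
]

BENIGN_SUSPICIOUS = "benign_suspicious"
MALIGNANT_SUSPICIOUS = "malignant_suspicious"
NON_VASCULAR = "non_vascular"

#: CFI = colour flow imaging, PDI = power Doppler imaging; the "A" prefix
#: marks the planewave ultrasensitive (AngioPLUS) coupling of each mode.
DOPPLER_MODES = ("CFI", "ACFI", "PDI", "APDI")

QUALITATIVE_GRADES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class VascularityMeasurement:
    """Replicate-averaged regional vascularity of one nodule in one mode."""

    vi_peripheral: float
    vi_central: float
    rvi: float
    suspicion: str
    n_replicates: int
    mode: str | None = None
    vi_overall: float | None = None


def detect_colour_pixels(image: np.ndarray, chroma_threshold: float = 10) -> np.ndarray:
    """Boolean mask of Doppler-signal (colour) pixels in an 8-bit RGB frame.

    A pixel is colour iff ``max(R,G,B) - min(R,G,B) > chroma_threshold``;
    greyscale pixels (R = G = B) have zero chroma and are never detected.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {image.shape}")
    channels = image.astype(np.int16)
    chroma = channels.max(axis=2) - channels.min(axis=2)
    return chroma > chroma_threshold


def compute_vi(colour_mask: np.ndarray, region_mask: np.ndarray) -> float:
    """Vascularity index: percentage of region pixels carrying colour."""
    colour_mask = np.asarray(colour_mask).astype(bool)
    region_mask = np.asarray(region_mask).astype(bool)
    if colour_mask.shape != region_mask.shape:
        raise ValueError(
            f"mask shapes differ: {colour_mask.shape} vs {region_mask.shape}"
        )
    area = int(region_mask.sum())
    if area == 0:
        raise ValueError("region mask is empty; cannot compute a vascularity index")
    return 100.0 * int((colour_mask & region_mask).sum()) / area


def measure_regions(
    image: np.ndarray,
    partition,
    chroma_threshold: float = 10,
) -> tuple[float, float, float]:
    """(peripheral VI, central VI, whole-ROI VI) of one frame under a partition."""
    colour = detect_colour_pixels(image, chroma_threshold)
    vi_p = compute_vi(colour, partition.peripheral_mask)
    vi_c = compute_vi(colour, partition.central_mask)
    vi_overall = compute_vi(colour, partition.roi_mask)
    return vi_p, vi_c, vi_overall


def _rvi_from_means(vi_p: float, vi_c: float) -> tuple[float, str]:
    if vi_c > 0:
        rvi = vi_p / vi_c
        return rvi, classify_rvi(rvi)
    if vi_p > 0:
        return float("inf"), BENIGN_SUSPICIOUS
    return float("nan"), NON_VASCULAR


def aggregate_replicates(
    replicates: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    mode: str | None = None,
    area_peripheral: int | None = None,
    area_central: int | None = None,
) -> VascularityMeasurement:
    """Average replicate (peripheral VI, central VI) pairs and form the RVI.

    The RVI is the ratio of replicate means (not the mean of per-replicate
    ratios). When the central mean is 0 but the peripheral mean is positive
    the RVI is +inf (benign-leaning); when both means are 0 the nodule is
    non-vascular.

    When the region pixel areas are supplied, the area-weighted overall VI
    is attached as well.
    """
    pairs = np.asarray(list(replicates), dtype=float)
    if pairs.size == 0:
        raise ValueError("no replicates supplied")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("replicates must be (vi_peripheral, vi_central) pairs")
    vi_p, vi_c = pairs.mean(axis=0)
    rvi, suspicion = _rvi_from_means(vi_p, vi_c)
    vi_overall = None
    if area_peripheral is not None and area_central is not None:
        total = area_peripheral + area_central
        vi_overall = (area_peripheral * vi_p + area_central * vi_c) / total
    return VascularityMeasurement(
        vi_peripheral=float(vi_p),
        vi_central=float(vi_c),
        rvi=float(rvi),
        suspicion=suspicion,
        n_replicates=len(pairs),
        mode=mode,
        vi_overall=vi_overall,
    )


def classify_rvi(rvi: float, threshold: float = 1.0) -> str:
    """RVI > threshold -> benign-suspicion; RVI <= threshold -> malignancy-suspicion."""
    if rvi < 0:
        raise ValueError(f"RVI must be non-negative, got {rvi}")
    return BENIGN_SUSPICIOUS if rvi > threshold else MALIGNANT_SUSPICIOUS


def classify_qualitative(grade: str) -> str:
    """Map a qualitative vascularity grade (I-IV) to a suspicion label."""
    if grade not in QUALITATIVE_GRADES:
        raise ValueError(f"unknown grade {grade!r}; expected one of {QUALITATIVE_GRADES}")
    return BENIGN_SUSPICIOUS if grade in ("I", "II") else MALIGNANT_SUSPICIOUS
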