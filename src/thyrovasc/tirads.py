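"""Rule-based EU TIRADS categorisation and the combined-assessment rule.

EU TIRADS assigns a malignancy-risk category from grey-scale ultrasound
features. High-risk features are irregular margins, marked hypoechogenicity
of a solid nodule, taller-than-wide shape, and microcalcifications; any one
of them puts a nodule in category 5. A mildly hypoechoic nodule without
high-risk features is category 4 (intermediate), a pure cyst or spongiform
nodule is category 2 (benign), and everything else is category 3 (low
risk). Category 1 (no nodule) cannot arise because inputs are nodules.

Two cut-offs are used for risk stratification: category >= 5 when the
grey-scale assessment stands alone, and category >= 4 when it is combined
with a Doppler vascularity assessment. The combined rule predicts
malignancy only when BOTH the TIRADS cut-off and the vascularity
malignancy-suspicion are met, which can only raise specificity and lower
sensitivity relative to either component.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vascularity import BENIGN_SUSPICIOUS, MALIGNANT_SUSPICIOUS, NON_VASCULAR

__all__ = [
    "COMPOSITIONS",
    "ECHOGENICITIES",
    "GreyScaleFeatures",
    "eu_tirads_category",
    "classify_tirads",
    "combine",
]

COMPOSITIONS = ("pure_cyst", "spongiform", "solid", "mixed")
ECHOGENICITIES = (
    "hyperechoic",
    "isoechoic",
    "mildly_hypoechoic",
    "markedly_hypoechoic",
    "anechoic",
)
_CUTOFFS = {"sole_ge5": 5, "combined_ge4": 4}


@dataclass(frozen=True)
class GreyScaleFeatures:
    """Grey-scale ultrasound features of one nodule.

    Mixed cystic-solid nodules are categorised by their solid-component
    features, following standard EU TIRADS practice.
    """

    composition: str
    echogenicity: str
    margins: str  # "smooth" or "irregular"
    taller_than_wide: bool
    microcalcifications: bool
    shape_oval: bool = True

    def __post_init__(self) -> None:
        if self.composition not in COMPOSITIONS:
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.echogenicity not in ECHOGENICITIES:
            raise ValueError(f"unknown echogenicity {self.echogenicity!r}")
        if self.margins not in ("smooth", "irregular"):
            raise ValueError(f"unknown margins {self.margins!r}")
        if self.composition == "pure_cyst" and self.echogenicity != "anechoic":
            raise ValueError("a pure cyst must be anechoic")


def eu_tirads_category(features: GreyScaleFeatures) -> int:
    """EU TIRADS category (2, 3, 4 or 5) from grey-scale features."""
    high_risk = (
        features.margins == "irregular"
        or features.taller_than_wide
        or features.microcalcifications
        or (
            features.echogenicity == "markedly_hypoechoic"
            and features.composition in ("solid", "mixed")
        )
    )
    if high_risk:
        return 5
    if features.echogenicity == "mildly_hypoechoic":
        return 4
    if features.composition in ("pure_cyst", "spongiform"):
        return 2
    return 3


def classify_tirads(category: int, cutoff: str = "sole_ge5") -> bool:
    """True (positive for malignancy) iff the category reaches the cut-off."""
    if category not in (2, 3, 4, 5):
        raise ValueError(f"EU TIRADS category must be in {{2,3,4,5}}, got {category}")
    try:
        threshold = _CUTOFFS[cutoff]
    except KeyError:
        raise ValueError(
            f"unknown cutoff {cutoff!r}; expected one of {tuple(_CUTOFFS)}"
        ) from None
    return category >= threshold


def combine(tirads_positive: bool, vascular_suspicion: str) -> str:
    """Combined prediction: malignant iff both assessments are suspicious.

    Non-vascular records must be excluded upstream and are rejected here.
    """
    if vascular_suspicion == NON_VASCULAR:
        raise ValueError(
            "non-vascular nodules are excluded from the combined assessment"
        )
    if vascular_suspicion not in (BENIGN_SUSPICIOUS, MALIGNANT_SUSPICIOUS):
        raise ValueError(f"unknown suspicion label {vascular_suspicion!r}")
    if tirads_positive and vascular_suspicion == MALIGNANT_SUSPICIOUS:
        return "malignant"
    return "benign"
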