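"""Run configuration shared by the pipeline stages and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable analysis parameters.

    offset_fraction
        ROI contraction defining the central region; 0.22 is the
        diagnostically optimal value for thyroid nodules.
    chroma_threshold
        Minimum max-min channel difference (8-bit) for a pixel to count as
        Doppler colour signal.
    tirads_cutoff
        ``sole_ge5`` for the stand-alone grey-scale assessment,
        ``combined_ge4`` when combining with a vascularity assessment.
    rvi_threshold
        RVI at or below which vascularity is called central-predominant
        (malignancy-suspicious).
    """

    offset_fraction: float = 0.22
    chroma_threshold: float = 10.0
    tirads_cutoff: str = "sole_ge5"
    rvi_threshold: float = 1.0
    ci_level: float = 0.95
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.offset_fraction <= 1.0:
            raise ValueError("offset_fraction must be in [0, 1]")
        if self.chroma_threshold < 0:
            raise ValueError("chroma_threshold must be non-negative")
        if self.tirads_cutoff not in ("sole_ge5", "combined_ge4"):
            raise ValueError(f"unknown tirads_cutoff {self.tirads_cutoff!r}")
        if self.rvi_threshold < 0:
            raise ValueError("rvi_threshold must be non-negative")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
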