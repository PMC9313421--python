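"""Write reproducible fixture bundles: phantom images, masks, cohort, manifest.

Layout under the output directory::

    images/<id>.png        8-bit RGB phantom frames
    masks/<id>_mask.png    single-channel masks, 0 = background, 255 = ROI
    image_truth.csv        exact per-region colour-pixel counts and areas
    cohort.csv             simulated nodule table
    manifest.json          every artefact with its seed and sha256 checksum
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .phantom import ImagePhantomSpec, generate_doppler_image

__all__ = ["write_fixture_bundle"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    output_dir: str | Path,
    image_specs: Sequence[ImagePhantomSpec] = (),
    cohort_spec: CohortSpec | None = None,
    image_ids: Sequence[str] | None = None,
) -> dict:
    """Write a bundle and return its manifest (also saved as JSON).

    ``image_ids`` names the image files (default ``img_000`` ...); using
    ``<nodule>_<mode>_<replicate>`` stems makes the bundle directly
    consumable by the quantification pipeline.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    if image_ids is None:
        image_ids = [f"img_{i:03d}" for i in range(len(image_specs))]
    if len(image_ids) != len(image_specs):
        raise ValueError("image_ids and image_specs differ in length")

    manifest: dict = {"artefacts": [], "cohort": None}
    truth_rows = []
    if image_specs:
        (out / "images").mkdir(exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
    for image_id, spec in zip(image_ids, image_specs):
        image, roi, truth = generate_doppler_image(spec)
        image_path = out / "images" / f"{image_id}.png"
        mask_path = out / "masks" / f"{image_id}_mask.png"
        iio.imwrite(image_path, image)
        iio.imwrite(mask_path, (roi * 255).astype("uint8"))
        truth_rows.append(
            {
                "image_id": image_id,
                "count_peripheral": truth.count_peripheral,
                "count_central": truth.count_central,
                "area_peripheral": truth.area_peripheral,
                "area_central": truth.area_central,
                "vi_peripheral": truth.vi_peripheral,
                "vi_central": truth.vi_central,
            }
        )
        for path in (image_path, mask_path):
            manifest["artefacts"].append(
                {
                    "file": str(path.relative_to(out)),
                    "seed": spec.seed,
                    "sha256": _sha256(path),
                    "spec": {k: v for k, v in asdict(spec).items()},
                }
            )
    if truth_rows:
        truth_path = out / "image_truth.csv"
        pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
        manifest["artefacts"].append(
            {"file": "image_truth.csv", "seed": None, "sha256": _sha256(truth_path)}
        )

    if cohort_spec is not None:
        cohort_path = out / "cohort.csv"
        generate_cohort(cohort_spec).to_csv(cohort_path, index=False)
        manifest["cohort"] = {
            "file": "cohort.csv",
            "seed": cohort_spec.seed,
            "sha256": _sha256(cohort_path),
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
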