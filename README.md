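# thyrovasc

Regional Doppler vascularity analysis for thyroid-nodule malignancy-risk
stratification.

Benign thyroid nodules tend to show predominantly *peripheral* blood flow on
Doppler ultrasound, while malignant nodules more often show *central* flow.
`thyrovasc` turns that observation into a quantitative pipeline for
researchers evaluating Doppler modes (colour flow imaging CFI, power Doppler
PDI, and their planewave-ultrasensitive "Angio" variants ACFI/APDI) against
grey-scale risk stratification:

1. **Offset segmentation** — a nodule ROI mask is split into a central core
   and a peripheral rim. A pixel is central when its Euclidean distance to
   the ROI boundary is at least a fraction (default **22%**) of the maximum
   inscribed distance.
2. **Vascularity index (VI)** — colour (Doppler-signal) pixels are detected
   by chroma (`max(R,G,B) − min(R,G,B) > 10`), and
   `VI = 100 · |colour ∩ region| / |region|` per region, averaged over the
   three replicate acquisitions per nodule and mode.
3. **Ratio vascularity index (RVI)** — `RVI = VI_peripheral / VI_central`
   (ratio of replicate means). `RVI > 1` ⇒ suspicious for benignity,
   `RVI ≤ 1` ⇒ suspicious for malignancy. Qualitative grades I–IV
   (exclusively/predominantly peripheral vs central) map the same way.
4. **EU TIRADS** — rule-based categories 2–5 from grey-scale features; a
   nodule is positive at category ≥ 5 alone, or at category ≥ 4 when
   combined (by logical AND) with a vascularity assessment.
5. **Diagnostics** — SEN/SPEC/PPV/NPV/FNR/FPR with exact Clopper–Pearson
   95% CIs, single-operating-point `AUROC = (SEN + SPEC)/2` with a
   Hanley–McNeil interval, exact McNemar, Cochran's Q, AUROC z-tests,
   Cohen's κ with proportion agreement, paired t and chi-square tests.

Because clinical Doppler images are rarely shareable, the package ships a
synthetic-data module: image phantoms with *exactly known* per-region
colour-pixel counts, and simulated cohorts reproducing the reference study
structure (94 nodules: 30 malignant / 64 benign; 40 cytologically equivocal:
9 / 31; three replicates per nodule per mode).

## Worked example

```python
import numpy as np
from thyrovasc import segmentation, vascularity
from thyrovasc.synthetic import ImagePhantomSpec, generate_doppler_image

spec = ImagePhantomSpec(target_coverage_peripheral=0.25,
                        target_coverage_central=0.10, seed=3)
image, roi, truth = generate_doppler_image(spec)

part = segmentation.partition_regions(roi, offset_fraction=0.22)
colour = vascularity.detect_colour_pixels(image, chroma_threshold=10)
vi_p = vascularity.compute_vi(colour, part.peripheral_mask)
vi_c = vascularity.compute_vi(colour, part.central_mask)
m = vascularity.aggregate_replicates([(vi_p, vi_c)])
print(f"VI_p={vi_p:.2f}  VI_c={vi_c:.2f}  RVI={m.rvi:.2f}  {m.suspicion}")
```

prints

```
VI_p=25.02  VI_c=10.02  RVI=2.50  benign_suspicious
```

— the measured VIs recover the phantom's painted coverages (25% peripheral,
10% central) to within the discretisation of single colour primitives, and
the RVI > 1 labels the predominantly peripheral pattern benign-leaning.

The command line mirrors the library:

```bash
thyrovasc simulate bundle/ --n-images 4 --seed 7   # phantoms + cohort
thyrovasc quantify bundle/images bundle/masks      # per-nodule VI/RVI table
thyrovasc evaluate bundle/cohort.csv               # performance per assessment
thyrovasc compare bundle/cohort.csv                # McNemar / Cochran Q / z-tests
thyrovasc check-reference                          # published-cell consistency
```

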