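# Methods

## The analysis model

A thyroid nodule's Doppler frame is modelled as a greyscale B-mode image
with pure colour overlaid wherever flow was detected. Since overlay colours
are chromatic and B-mode pixels satisfy R = G = B, a chroma rule
(`max(R,G,B) − min(R,G,B) > threshold`, default 10/255) separates signal
from background; the threshold absorbs mild compression/anti-aliasing noise
at overlay edges. The vascularity index of a region is the colour-pixel
percentage of that region. Raising the threshold can only shrink the colour
mask, so every VI is monotone non-increasing in the threshold.

### Offset segmentation

The central region is the set of ROI pixels whose Euclidean distance to the
ROI boundary is at least `offset_fraction` × the maximum such distance; the
peripheral rim is the complement within the ROI. Geometry conventions that
the implementation and the test oracle share exactly:

- boundary = ROI pixels 4-adjacent to background, with the frame edge
  treated as background;
- distances are measured to boundary *pixels* (so the deepest pixel of a
  disk of radius r sits at distance ≈ r − 1, and a 22% offset keeps a
  central disk of ≈ (1 − 0.22)² ≈ 0.61 of the area, slightly less after
  discretisation);
- ties on the threshold go to central (`≥`), which makes offset 0 map the
  entire ROI to central and offset 1 keep the non-empty argmax set.

The published protocol does not define the offset geometry beyond "offset
of 22%"; distance-to-boundary fraction was chosen as the default because it
is well defined for arbitrary (including non-convex and multi-component)
shapes. A `contour_scale` alternative (shrink toward the centroid by
1 − offset) is available for sensitivity analysis; it agrees with the
default on near-circular ROIs and diverges on elongated or non-convex ones.
Masks with several connected components are processed as one mask with a
warning, since the upstream protocol excludes multinodular images without a
clearly isolated nodule.

### RVI and classification

Per-nodule regional VIs are arithmetic means over the replicate
acquisitions (three per mode by default), and RVI is the ratio of those
means — not the mean of per-replicate ratios, which would be ill-defined
whenever a single replicate has zero central signal. Degenerate cases:
peripheral signal only ⇒ RVI = +∞, classified benign-leaning; no signal at
all ⇒ non-vascular, excluded from evaluation with a logged count (the
clinical protocol excludes non-vascular nodules at enrolment). The decision
rule is RVI > 1 ⇒ suspicious for benignity, RVI ≤ 1 ⇒ suspicious for
malignancy; the threshold is configurable (`rvi_threshold`).

### EU TIRADS and combination

Categories are assigned by rule: any high-risk feature (irregular margins,
taller-than-wide, microcalcifications, marked hypoechogenicity of a
solid/mixed nodule) ⇒ 5; otherwise mild hypoechogenicity ⇒ 4; pure cyst or
spongiform ⇒ 2; else 3. Mixed nodules follow their solid component.
Cut-offs: category ≥ 5 for the stand-alone grey-scale assessment, ≥ 4 for
combination. The combined prediction is the logical AND of the TIRADS
cut-off and the vascularity suspicion, so on any cohort combined
specificity ≥ each component's and combined sensitivity ≤ each component's
(tested as an invariant).

### Statistics

- Binomial rates (SEN, SPEC, PPV, NPV, FNR, FPR) in percent with exact
  Clopper–Pearson intervals from beta quantiles; PPV/NPV are reported as
  undefined when no positive (resp. negative) calls exist.
- Every assessment here is a single-operating-point binary test, so the
  AUROC is the trapezoid (SEN + SPEC)/2. This estimator reproduces every
  internally consistent published AUROC cell; its CI uses the
  Hanley–McNeil standard error (the original CI method is unstated, so
  published AUROC CIs are not reproduced).
- McNemar defaults to the exact two-sided binomial form,
  p = min(1, 2·P(X ≤ min(b, c))), appropriate for the small discordant
  counts a 94-nodule cohort produces; a continuity-corrected chi-square
  variant is available. Zero discordant pairs ⇒ p = 1 with a flag.
- Cochran's Q (statsmodels) with all-concordant subjects dropped first;
  with k = 2 it reduces to the uncorrected McNemar chi-square.
- The AUROC z-test uses independent Hanley–McNeil errors; pairing of the
  two tests on the same nodules is not modelled, and the result is
  labelled `auroc_z_unpaired` accordingly.
- Cohen's κ is unweighted, reported with the raw proportion agreement;
  both raters constant-and-equal ⇒ κ undefined (NaN), agreement 1.
- No multiple-testing adjustment is applied, matching the reference
  analysis plan.
- Displayed rounding is half-away-from-zero, one decimal for percentages
  and two for AUROC, as in the published tables.

## Synthetic data

### Image phantoms

A phantom emulates a captured Doppler still: a greyscale background (flat,
or multiplicative Rayleigh speckle on a smoothed base), an elliptical,
circular or harmonically perturbed "blob" ROI, and colour primitives (disks
of radius 1–3 px, red/blue or orange palettes with chroma ≥ 100) painted
uniformly at random inside each target region until the requested coverage
fraction is met — the final primitive may overshoot by at most its own
area. Primitives are clipped to their region, so the recorded painted-pixel
counts are exact ground truth, and tests recount them independently on the
emitted image with the chroma rule. What phantoms do *not* emulate:
acoustic physics, velocity aliasing, colour maps blending into the
greyscale, probe/operator variability, or vessel-like connectivity of the
flow signal. Passing recovery tests therefore demonstrates the
arithmetic of segmentation and counting, not robustness to real acquisition
artefacts.

### Simulated cohorts

The default cohort reproduces the reference structure: 94 nodules
(30 malignant/64 benign), 40 equivocal (9/31), three replicates per nodule
per mode. Per mode, two malignancy-suspicion indicators are drawn —
qualitative grading and the RVI rule — Bernoulli(SEN) in malignant and
Bernoulli(1 − SPEC) in benign nodules, using the published all-nodule
operating points as defaults (qualitative: CFI 53.3/92.2, ACFI 80.0/82.8,
PDI 46.7/95.3, APDI 83.3/81.3; RVI: 56.7/81.3, 60.0/73.4, 46.7/65.6,
66.7/73.4). Indicators are independent across modes given truth by
default; a shared-latent Gaussian-copula correlation (`mode_correlation`)
is available. Equivocal flags are assigned independently of the indicators
given truth.

TIRADS categories are drawn from per-truth distributions chosen so the
marginal cut-off rates match the published operating points under
conditional independence: P(cat 5) = 0.833/0.500 (malignant/benign) and
P(cat ≥ 4) = 0.921/0.834, the latter derived from the combined
(EU + qualitative APDI) operating point via the AND rule. The remaining
mass is split between categories 3 and 2.

Replicate VI pairs are drawn around nodule-level means consistent with the
nodule's RVI indicator: the smaller regional VI uniform on [8, 35] VI
points (typical of the published per-mode means of 26–57), the larger
exceeding it by a ratio in [1.3, 3] (capped at 95), plus Gaussian replicate
jitter (sd 3 VI points) truncated to [0, 100]. If jitter would flip the
replicate-mean RVI against the indicator — rare given the ratio margin —
the jitter alone is redrawn deterministically, keeping the emitted table
internally consistent. Real VI distributions are right-skewed and
heteroscedastic; this generator makes no attempt to match their shape, only
the classification structure the evaluation consumes.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical spec + seed gives bit-identical
images and tables.

## Published-value reconstruction

`thyrovasc.reference` stores the published SEN/SPEC/PPV/NPV/AUROC of all 22
assessment × subset cells. Since PPV, NPV and the one-point AUROC are
deterministic in (SEN, SPEC, class sizes), each cell is recomputed and
compared at printed precision. Three cells fail their own internal
arithmetic and are flagged, not reproduced: the equivocal grey-scale AUROC
(printed 0.62 vs (88.9 + 38.7)/200 = 0.64), the equivocal CFI qualitative
AUROC (0.79 vs 0.78), and the whole combined EU + APDI-RVI all-nodules
column, whose printed sensitivity 58.1% is impossible with 30 malignant
nodules (it implies a denominator of 31).

## Problem sizes

The test suite and the acceptance script run on: oracle masks ≤ 64×64
(exhaustive boundary-distance recomputation), 200–256 px phantoms, cohorts
of 94 nodules for structural tests, and one 100,000-nodule cohort
(prevalence-preserving scale-up, 31,915 malignant) for operating-point
recovery within ±1 percentage point. Clopper–Pearson coverage is checked
over 2,000 simulated binomials (n = 30, p = 0.8) against a conservative
93% floor.

## Known limitations

- The offset geometry is a design choice; other plausible definitions
  (fraction of an equivalent radius, per-ray local radius) would shift the
  central/peripheral split on non-circular nodules.
- The AUROC z-test ignores pairing and is anti-conservative when two
  assessments are positively correlated on the same nodules.
- Simulated cohorts draw equivocal-subset indicators from the all-nodule
  operating points, so published equivocal-subset sensitivities that
  differ from the overall ones are not targeted by the simulation (they
  are still covered by the deterministic reconstruction).
- Qualitative grading is treated as an input (simulated or supplied);
  the package does not grade vascularity patterns from pixels.
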