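# Methods

## Problem setting

One patient presents `L` lesions (one primary gastric tumor, `lesion_id 0`,
plus up to five target lesions) observed at up to five CT timepoints
(baseline BL and follow-ups 1F–4F). The outcome is right-censored overall
survival in months. The package predicts `risk = P(OS < 12 months)` from the
lesion patches and, in a parallel instantiation, from the longitudinal
tumor-marker panel; a Cox nomogram fuses both with RECIST and clinical
covariates.

## ROI preprocessing

For each bounding box (0-based pixel coordinates, top-left origin, half-open
extents, box size fixed at its baseline value across timepoints):

1. **Expansion** by 1.5× about the box center (widths rounded to the nearest
   integer, odd margins put the extra pixel on the trailing side), clipped
   per axis to the image.
2. **Square padding** to the minimum circumscribed square, split equally
   with the extra pixel trailing; the pad value is the window minimum, so
   padding renders as the darkest displayable tissue rather than a bright
   artifact.
3. **Windowing**: lung lesions use level −400 / width 1500, all other sites
   level 50 / width 350; the window maps linearly to [0, 1] with clipping.
   Only these two windows are distinguished because they are the two
   standard reads for thoracic vs abdominal soft tissue.
4. **Resampling** to a fixed square (default 224, reduced for desk-scale
   runs) with bilinear interpolation, stacking the slices below/at/above the
   annotation as 3 channels; at a volume boundary the missing neighbour is
   replaced by the central slice.

Training-time augmentation is a joint rotation of the 3-channel stack by a
uniform angle in ±30°, bilinear, filled with the patch minimum. The three
channels rotate together because they are one anatomical context.

Contrast phases: liver lesions use the venous phase only; other sites prefer
venous and fall back to arterial. One phase is selected per lesion at load
time; the model itself is agnostic and would accept both phases as separate
objects.

**Lesion measurement.** Boxes keep their baseline size, so per-timepoint
diameters (needed by RECIST/TB-delta and by target-lesion selection) are
measured from the image: the expanded ROI at the annotated slice is smoothed
(Gaussian, σ=1 px), thresholded midway between the border-ring median
(background) and the 99.5th percentile (lesion), and the largest connected
component's longest bounding-box extent is the diameter; its pixel count is
the area. An explicit diameter table can be supplied instead when
measurements come from elsewhere.

## Model

* Feature extractor: a miniature ResNet-style CNN (strided stem + three
  stride-2 residual stages + global average pooling + linear head). It is
  initialized from a fixed seed and kept frozen by default: with global
  average pooling its embeddings code lesion size and contrast robustly, and
  freezing makes desk-scale CPU training fast and deterministic. A config
  switch (`train_extractor`) exists for end-to-end training; channel widths
  and stage count are configurable up to a full-size instantiation.
* Features are standardized per dimension with training-cohort statistics
  stored in the checkpoint. A per-vector LayerNorm is deliberately *not*
  used here: lesion size is largely magnitude-coded in pooled CNN features,
  and per-vector normalization erases it.
* TH-former and OH-former: pre-norm transformer encoders, default 2 layers ×
  4 heads, `d = 128` (64 at desk scale), feed-forward width `2d`. The
  temporal position embedding is a learned `(5, d)` table; disabling it
  makes the temporal level order-invariant (verified by a property test).
  The aggregation token is a learned `d`-vector shared across patients.
* Masking: invalid keys receive additive `−∞` attention logits, giving
  exactly zero weight after the softmax (not merely small); masked slots
  carry zero sentinel embeddings; the TH output is the mask-weighted mean
  over valid timepoints; padded lesions are zeroed and masked at the OH
  level. Consequences verified as invariants: outputs are bit-identical
  under changes of masked content, and invariant (1e-5) to lesion
  permutation and appended padding lesions.
* Head: `d → d/2 → 2` MLP with ReLU; softmax over [good, poor]; the reported
  risk is the poor-class probability. Sign convention: high risk means
  predicted OS < 12 months, and patients with risk above the cutoff form the
  high-risk group.

The marker model (TDLM) reuses the skeleton: each marker is one object whose
per-timepoint `(normalized value, marker identity)` pair is linearly
projected into `R^d`; missing values are masked exactly like missing scans.

## Losses and training

* `l_ce`: mean binary cross-entropy over patients with a defined class —
  poor = death observed before 12 months, good = OS ≥ 12 months regardless
  of censoring. Patients censored before 12 months have an undefined class
  and are excluded from `l_ce` but retained in `l_surv`, where their risk
  ordering is still informative.
* `l_surv`: negative Cox partial log-likelihood (Breslow ties) of the risk
  score over the mini-batch, averaged over events; it is invariant to adding
  a constant to all scores and is computed on the poor-minus-good logit
  margin. Cox partial likelihood is used because the requirement is exactly
  a ranking loss over censored outcomes, and it is the canonical one. A
  separate `surv_batch_size` can enlarge the ranking batch beyond the
  classification batch.
* Total loss `l_ce + l_surv` with unit weights by default (configurable).
* Optimizer: Adam, fixed learning rate 5e-3, batch 32, 10 epochs, all seeded;
  training is deterministic on a single thread. Batches with no applicable
  term (no events, or all-indeterminate labels) skip that term. NaN loss
  aborts with a diagnostic.
* Training always sees up to four follow-ups; evaluation horizons (BS / 1F /
  2F / 4F) are enforced at prediction time by masking, so `forward` never
  errors on missing data — a patient without a second follow-up scored at
  the 2F horizon is exactly the 1F prediction.

## Phantom cohort generator

The generator emulates the study conditions so that ground truth exists for
every downstream stage:

* **Latent risk** `z ~ N(0, 1)` per patient.
* **Survival**: Weibull with shape 1.2, median 16 months at `z = 0`
  (matching the landmark trial median OS for this population), proportional
  hazards with log-hazard `hazard_coef · z` (default 1). Censoring is an
  independent Weibull of the same shape whose scale is solved (exactly, via
  the same-shape reduction to exponential odds) so the marginal censoring
  fraction equals `censoring_rate` (default 0.25).
* **Lesions**: one stomach primary plus 1–5 targets (sites drawn
  lymph node 0.50 / liver 0.35 / lung 0.15, the most frequent metastatic
  sites in this disease); baseline diameters uniform 12–35 mm (primary
  20–40 mm), all above the 10 mm target-lesion threshold. Log-diameter
  follows a random walk with drift `0.12·z` per timepoint (lesion-level
  drift noise 0.04, step noise 0.03), clipped to 0.5–1.6× baseline so the
  lesion stays inside its fixed box. High risk ⇒ growth, low risk ⇒
  shrinkage, which is what gives RECIST/TB-delta and the temporal model a
  recoverable signal.
* **Rendering**: soft-edged rotated ellipses (eccentricity 0.85, fixed
  orientation per lesion) on site-dependent backgrounds (lung ≈ −800 HU,
  abdominal sites 0–70 HU) with Gaussian HU noise (σ = 15), three slices per
  lesion with a reduced cross-section on the neighbours; each lesion lives in
  its own slice band of the patient volume, so lesions never overlap.
* **Follow-up dropout** is monotone: after baseline, each next follow-up is
  reached with probability `1 − followup_missing_prob` (default 0.85), and a
  missing follow-up truncates all later ones, mirroring clinical truncation.
* **Markers**: three generic channels, log-normal levels whose log-trend over
  time is proportional to `z` (slopes +0.8, +0.5, −0.6), with 10% random
  missingness. Marker identities/units are generic because the package is
  marker-agnostic; normalization uses training-cohort mean/variance.
* **Clinical covariates**: sex (77% male), HER2 status (75% `3+`), therapy
  line — frequencies chosen to resemble a typical HER2-positive stage IV GC
  cohort.

What the generator does **not** emulate: realistic CT texture, organ
anatomy, registration error between timepoints, contrast-phase differences,
non-PH survival, informative censoring, or marker assay quirks. Passing
tests therefore demonstrate that the implementation recovers known signal
under the stated generative assumptions — not clinical performance.

## Evaluation suite

* Harrell's C-index (ties counted ½) with percentile-bootstrap 95% CIs
  (2000 replicates, seeded); verified exactly against pair enumeration.
* One-year AUC: binary AUC of death-before-12-months vs survival-beyond,
  excluding patients censored before 12 months — chosen to match the model's
  binary label; an IPCW time-dependent AUC is a possible alternative and the
  exclusion rule is the documented default.
* Youden cutoff: maximizes sensitivity + specificity − 1 over midpoints of
  adjacent distinct training scores, lowest threshold on ties; the training
  cutoff is frozen for all validation cohorts.
* Kaplan–Meier product-limit curves, two-group log-rank test, and the hazard
  ratio from a univariate Cox fit on the binary risk group.

## Nomogram

Cox partial-likelihood fit (lifelines) of `ldlm_score`, optional
`tdlm_score`, RECIST (ordered dummies with objective response CR/PR as
reference), `sex_male`, `her2_3plus`. Missing markers are handled by the
refitted without-TDLM variant rather than imputation. One-year survival is
`S0(12)^exp(lp − mean lp)` with the Breslow baseline at 12 months stored in
the model. Points scale each covariate's `β·x` contribution to start at 0
over the training range, with the widest span worth 100 points; the mapping
is affine and exactly invertible. Calibration uses deciles of predicted
one-year survival vs the Kaplan–Meier observed survival per bin, with a
Hosmer–Lemeshow chi-square on the implied event counts (df = bins − 2,
undersized bins merged and logged).

## Explanation

Temporal importance is the last TH-former layer's attention, averaged over
heads and valid queries, renormalized over valid timepoints; inter-lesion
attention is the last OH-former layer's aggregation-token row and
object-object block, head-averaged and renormalized, aggregated into a
site × site organ matrix. Group-level reports average patients above/below
the frozen cutoff and are descriptive, not hypothesis tests. GradCAM
backpropagates a class logit to the last convolutional feature maps and
upsamples the ReLU-rectified gradient-weighted sum, max-normalized; an
all-nonpositive map is returned as all-zero and flagged rather than
renormalized.

## Numerical choices and scales

* float64 throughout the model; masking uses true `−∞` so masked attention
  is exactly zero; softmax is max-shifted; the Cox loss uses a risk-set
  matrix with max-shifted exponentials.
* Desk-scale defaults used by the tests and the acceptance script: 64×64
  patches, `d = 64`, 300 training / 100 held-out patients, 10 epochs —
  small enough for single-CPU runs while leaving the latent-risk signal
  clearly recoverable (held-out C-index ≈ 0.6–0.67 against a ceiling of
  ≈ 0.73 for the true latent risk on the same cohort).
* The frozen extractor seed is decoupled from the training seed, so the
  backbone is shared across runs and per-seed variation reflects the
  trainable components.

## Limitations

* The extractor is frozen by default; end-to-end CNN training on real CT
  would need the full-size configuration and more compute.
* Image-based diameter measurement assumes one dominant bright lesion per
  ROI; overlapping or hypodense-on-bright lesions would need a different
  rule.
* The one-year AUC ignores censoring-time information (exclusion, not
  IPCW); bootstrap CIs are percentile, not BCa.
* RECIST is the diameter-sum core only: no nodal short-axis rules,
  non-target lesions, or confirmation scans; new lesions are an input flag.
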