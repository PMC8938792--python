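# Methods

This note documents the models and procedures implemented in
`sinusvol`, the parameters that matter, what the synthetic data does
and does not emulate, and the numerical choices made where the design
was open.

## 1. Scores

For each of the 12 sinonasal regions r (paired maxillary, anterior
ethmoid, posterior ethmoid, frontal, sphenoid sinuses and ostiomeatal
complexes, OMC), the segmented cavity is partitioned by intensity into
air and disease voxels and

* **VMLMs** (volume-based modified Lund-Mackay score):
  `vmlms_r = 2 · disease_r / (air_r + disease_r)`, summed over regions;
  continuous on [0, 24].
* **TLMs** (automated traditional score): sinuses grade 0 below a
  `partial_low` ratio, 2 above `complete_high`, otherwise 1; OMC grades
  0 or 2 (2 when more than half opacified); summed to an integer on
  [0, 24].

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `hu_threshold` | −400 HU | air/disease split; sits far from both air (≈ −1000 HU) and soft tissue (≈ +40 HU), so the split is insensitive to realistic noise. The discrimination rule for air vs disease is an interpretation — the underlying rubric is visual — and is therefore exposed in every API. |
| `partial_low`, `complete_high` | 0.05, 0.95 | numeric surrogates for the categorical "no / partial / complete opacification" rubric, which has no published cut-offs. |
| OMC rule | 0/2 at ratio 0.5 | the standard rubric scores OMC binary; its VMLMs contribution uses the same 2·ratio rule as the sinuses. |

Volumes are reported in mL (= cm³); a voxel contributes the product of
its spacings in mm divided by 1000.

Invariants enforced and tested: `air + disease = total` exactly in
voxel counts; totals equal the sum of sub-scores exactly; VMLMs is
monotone in any region's disease fraction and bounded in [0, 24]; when
every ratio is 0 or 1 the two scores coincide.

## 2. Segmentation network

2D per-slice segmentation of coronal slices, stacked to 3D (3D
convolutions are a non-goal).  The architecture, sized by `SegConfig`:

* Encoder of `depth` stages (default 3 for the phantom task; stage i
  has `base_width · 2^i` channels).  Each stage is a
  depthwise-separable block (3×3 depthwise + 1×1 pointwise, each with
  batch norm and ReLU) followed by a squeeze-and-excitation block
  (global-average-pool squeeze; C→C/r, Mish, C/r→C, logistic-gate
  excitation; channel-wise rescale), wrapped in a residual with a
  projection shortcut where shape changes.  Stages after the first
  downsample by stride 2, so the bottleneck sits at 1/2^(depth−1)
  resolution.
* ASPP at the bottleneck: one 3×3 convolution per dilation rate plus an
  image-level pooled branch, concatenated and fused 1×1.  The
  full-scale default rates are (1, 6, 12, 18); the tiny phantom
  configuration uses (1, 2, 4) to match its 1/4-resolution bottleneck
  (a rate-18 kernel would wrap a 12-pixel feature map).
* Decoder: bilinear upsampling to each skip stage's resolution,
  concatenation with the encoder features, a depthwise-separable block,
  and a final 1×1 head emitting per-class logits at input resolution
  for any input size (odd sizes use ceil-division downsampling and
  resize-to-recorded-size upsampling).

Input channels: intensity (scaled by 1/1000) plus three normalised
coordinate ramps (row, column, slice position).  Convolutions are
translation-equivariant, but left/right cavities differ only by
location, so some absolute-position signal is necessary; coordinate
channels provide it explicitly and cheaply.

Training: Adam (lr 3·10⁻³ for the tiny config), pixelwise
cross-entropy with median-frequency class balancing (weights
`(median_freq/freq_c)^0.5`, capped at 10, renormalised to mean 1) and
an optional soft-Dice term (weight 0.5 in the pipeline recipe, 0 by
`TrainConfig` default).  Balancing matters: the ethmoid and OMC
cavities occupy < 0.5 % of pixels and collapse to background under
plain cross-entropy.

The network runs on `sinusvol.nn`, a compact numpy engine written for
this package: convolutions are evaluated tap-by-tap as BLAS `einsum`s
(fast for 3×3 kernels at ≤ 128 px), and every layer implements an
explicit backward pass validated against central finite differences in
float64.

## 3. Semi-supervised self-training

Given labelled and unlabelled pools:

1. **Split** — labelled subjects split `floor(0.8·n)` train / rest
   validation; a configurable fraction of the unlabelled pool goes to
   self-training, the remainder to test.  Test subjects never enter
   training (asserted).
2. **Warm-up** — supervised training on the labelled training pool.
3. **Per round** (default 3 rounds; the pipeline uses 2):
   pseudo-label the self-training pool (per-pixel argmax, keep pixels
   with max probability ≥ τ, default 0.9; the rest are ignored);
   compute per-slice cross-entropy over the combined pool and fit a
   two-component Gaussian mixture to the min–max-normalised losses by
   EM (components initialised at the 25th/75th percentiles, variance
   floor 10⁻⁶, tolerance 10⁻⁶, ≤ 200 iterations — deterministic, with
   a per-iteration log-likelihood trace asserted non-decreasing);
   retrain on labelled + clean (posterior ≥ 0.5 under the lower-mean
   component) pseudo-labelled slices.  Noisy slices are excluded from
   the supervised term; an optional entropy-minimisation term
   (weight λ, default 0) can be applied to them — hard pseudo-labels
   already minimise entropy implicitly.
4. Pseudo-labels are refreshed once per round (labels follow the
   current model; per-epoch refresh is available via the round
   configuration).

Degenerate cases: identical losses collapse the mixture to one
cluster, all samples clean; an empty self-training pool reduces a
round to plain supervised training (tested step-for-step).

The mixture operates on per-slice losses (per-subject is a
straightforward aggregation the caller can do); slices, not subjects,
are the unit the loss is computed on.

## 4. Synthetic phantoms and cohorts

A phantom is a voxel grid (default 48×48×40 at 2 mm for cohort work;
spacing is free) containing 12 ellipsoidal cavities inside a 2-voxel
bone shell, surrounded by soft tissue.  Intensities: air −1000,
mucosa/disease +40, bone +700, background 0, Gaussian noise σ = 15 —
a plausible CT scale chosen once; only the air/soft-tissue contrast
matters downstream.  Disease fills each cavity from the wall inward
(mucosal-thickening pattern): cavity voxels are sorted by Euclidean
distance to the wall (ties by lexicographic index) and the closest
`round(fraction · n)` become disease, so the realised fraction is
exact to quota rounding and fully deterministic.  Identical spec and
seed give bit-identical output.

Region placement uses per-region allocation boxes, pairwise disjoint
by construction and mirrored left/right; ellipsoid radii are sized
from the target volume and capped to the (jittered) box, so cavities
can never collide regardless of the drawn volumes.  Consequence: very
large volume draws are realised slightly smaller than requested — the
voxel-counted ground truth is always the authority.  The OMC has no
published volumetric definition; it is modelled as a small 13th/14th
cavity pair (nominal 0.2 mL) as a documented convention.

Cohorts: sex ~ Bernoulli(111/175); age, height and weight drawn from
the published sex-specific means/SDs (weight partially mediated by
height).  Cavity volumes are linear-Gaussian in height with a direct
male offset; the height coefficient carries 70 % of the published
male–female mean difference and the offset the remaining 30 %, chosen
so group means match the published table in expectation for any
setting of `height_coef_scale` (0 removes the height effect for null
tests, shifting the difference wholly onto the offset).  Residual SD
is 0.8 of the published overall SD.  Opacification fractions are Beta
draws (concentration 8) around the group means implied by the
published per-region sub-scores, shifted per subject by a shared
logit-scale severity latent (SD 1.0) — severities correlate across
sinuses in CRS, and without this coupling no score could discriminate
anything at subject level.  Surgery ~ Bernoulli(50/175) selects the
high-opacification group.  SNOT-22 baseline increases with mean
opacification; surgical subjects respond (≥ 25 % reduction) with
probability `0.6 + 2.5·(mean ratio − group mean)`, so response is
coupled to *continuous* opacification — which is exactly why the
continuous VMLMs out-discriminates the coarse TLMs on these cohorts.

What the phantoms do **not** emulate: anatomical shape, partial-volume
and beam-hardening artifacts, inter-scanner variability, registration
error, and annotation noise.  Passing tests therefore demonstrate the
correctness of the pipeline's logic and its recovery of known ground
truth — not clinical segmentation performance on real CT.

## 5. Problem sizes and numerical choices

The test and acceptance runs use deliberately small study sizes chosen
as this package's own scaled-down study design: 40 training + 20 test
phantoms for supervised evaluation; 5 labelled + 40 unlabelled for the
self-training comparison (paired over 3 seeds against a
supervised-only continuation from the identical warm-up state);
500-subject cohorts for covariate-recovery statistics.  Training
samples every second coronal slice; evaluation segments every slice of
every test volume and compares in 3D.

Other numerical choices: 'same' padding with ceil-division output
sizes; bilinear resizing with align-corners weights and an exact
adjoint backward; He initialisation; batch norm with momentum 0.1 and
ε 10⁻⁵ (batches of < 2 samples are skipped); softmax cross-entropy in
float64 accumulation with a 10⁻¹² probability floor; marching-cubes
meshes are re-oriented outward before volume computation.  The ROC is
an explicit threshold sweep whose trapezoid AUC equals the
Mann–Whitney rank statistic exactly; the Youden cut-point breaks ties
toward higher specificity and is reported as the midpoint between
adjacent observed scores (integer scores yield half-integer
cut-points).  The Welch t-test is the two-sample default (pooled
variance available); no multiple-testing correction is applied, and
α = 0.05.

## 6. Known limitations

* The numpy engine targets tiny models; it is single-threaded per
  operation and keeps full activation caches, so it does not scale to
  clinical image sizes.
* Mean Dice/MIoU exclude classes absent from both prediction and
  reference and count classes absent from only one side as 0 — one of
  several reasonable conventions; it is documented here because
  published figures rarely state theirs.
* The automated TLMs derives from whole-region volumetric ratios; a
  per-slice reading mode would mimic a radiologist's single-plane
  assessment more closely and can be built from `reslice_coronal` +
  `region_volumes` on single-slice stacks.
* Cohort realism is calibrated to one published summary table;
  correlations not printed there (e.g. age–volume) are not modelled.
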