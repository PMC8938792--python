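# sinusvol

Automated 3D volumetric scoring of sinus CT for chronic rhinosinusitis
(CRS), built and validated end-to-end on synthetic phantoms with exact
ground truth.

The traditional Lund-Mackay score (TLMs) grades each of 10 paranasal
sinuses 0/1/2 and the two ostiomeatal complexes 0/2 by visual
inspection, for a total of 0–24.  Because grade 1 covers everything
from a mucosal rim to near-complete opacification, TLMs correlates
weakly with symptoms.  This package implements the volume-based
modification: segment every sinonasal region in 3D, split each cavity
into air and disease voxels, and score

    VMLMs_r = 2 · V_disease,r / V_total,r        (per region, ∈ [0, 2])
    VMLMs   = Σ_r VMLMs_r                         (12 regions, ∈ [0, 24])

a continuous score on the same 0–24 scale, alongside an automated TLMs
derived from the same opacification ratios.

It is aimed at researchers in medical image analysis who want a fully
self-contained, CPU-only reference implementation of the whole chain:

* **`sinusvol.phantom`** — seeded generator of head-CT-like volumes with
  12 disjoint labelled cavities (maxillary, anterior/posterior ethmoid,
  frontal, sphenoid, ostiomeatal complex; left/right), wall-inward
  opacification with voxel-exact ground truth, and whole synthetic
  cohorts whose covariate–volume structure (sex dimorphism, height
  correlation, surgical-group opacification, symptom response) follows a
  published 175-subject reference cohort.
* **`sinusvol.segnet`** — the segmentation network: an encoder–decoder
  built from depthwise-separable convolutions, squeeze-and-excitation
  channel gating (Mish-activated bottleneck), residual skips, an atrous
  spatial-pyramid-pooling bottleneck and a bilinear-upsampling decoder
  with encoder skips.  Runs on a compact numpy engine with hand-derived
  backward passes; tiny configurations train on one CPU in minutes.
* **`sinusvol.semisup`** — semi-supervised self-training: 8:2 labelled
  splits, confidence-filtered pseudo-labels (threshold τ), a
  two-component Gaussian-mixture split of per-slice losses into
  clean/noisy, and iterated retraining.
* **`sinusvol.volumetrics`** — stacking per-slice segmentations into 3D,
  per-region total/air/disease volumes in mL, VMLMs and automated TLMs,
  and marching-cubes surface meshes.
* **`sinusvol.evalstats`** — pixel accuracy, Dice, MIoU, per-region
  agreement tables, ROC/AUC with Youden cut-points, the ≥25% SNOT-22
  responder rule, and the t-test/ANOVA/OLS battery.
* **`sinusvol.cli` / `sinusvol.pipeline`** — a thin `sinusvol` command
  wiring everything into a reproducible pipeline with a hashed artifact
  manifest.

## Worked example

`examples/score_subject.py` generates one phantom and scores it from
its label map and intensity volume:

```
region    ratio  VMLMs  TLMs
Max-L     0.607  1.214     1
Max-R     0.895  1.790     1
AE-L      0.795  1.589     1
...
OMC-R     0.455  0.909     0

VMLMs total: 11.49   (truth 11.49)
TLMs  total:    10   (truth 10)
```

Every sinus here is partially opacified, so TLMs assigns ten
indistinguishable 1s; VMLMs resolves the difference between the 17%
frontal and the 90% maxillary involvement.  The recovered VMLMs matches
the generator's ground truth because air/disease voxel counting is
exact up to boundary noise.

The other examples each exercise one capability and print what they
compute: `generate_phantom.py` (exact per-region volumetry),
`train_segmenter.py` (supervised training to high held-out Dice),
`self_training.py` (pseudo-label rounds lifting validation Dice far
above a 4-labelled-subject warm-up), and `cohort_statistics.py`
(sex-dimorphism t-test, height regression, and a responder ROC —
AUC ≈ 0.89 for VMLMs on the default cohort).

The same pipeline is scriptable from the shell:

```bash
sinusvol phantom generate --n 5 --seed 1 --out phantoms/
sinusvol pipeline run --seed 1 --out run/
sinusvol score --labels run/../S0000_labels.nii.gz \
               --image  phantoms/S0000_volume.nii.gz --out score.json
```

## Scope

Anatomically realistic sinus shapes, DICOM handling, scanner-artifact
simulation and GPU-scale training are out of scope; the phantom's
ellipsoidal geometry is deliberately simple, because volumetry and
scoring only require disjoint labelled cavities with controllable
fill.  See `docs/methods.md` for the model, its assumptions and the
design decisions.
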