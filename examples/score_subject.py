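"""Volumetric Lund-Mackay scoring of a segmented subject.

Scores a phantom from its (here: ground-truth) label map and intensity
volume: per region, air and disease voxels are split by a -400 HU
threshold, the VMLMs sub-score is twice the disease-to-total ratio,
and the automated TLMs grades each sinus 0/1/2 (OMC 0/2).  The printed
totals are on the usual 0-24 Lund-Mackay scale; VMLMs is continuous,
so it resolves partial opacification that TLMs lumps into grade 1.
"""

from sinusvol import generate_cohort, generate_phantom, score_subject, vmlms

record, spec = generate_cohort(1, seed=11)[0]
volume, labelmap, ground_truth = generate_phantom(spec)

score = score_subject(labelmap, volume)
truth = vmlms(ground_truth)

print(f"{'region':8s} {'ratio':>6s} {'VMLMs':>6s} {'TLMs':>5s}")
for r in score.reports:
    print(f"{r.region_id:8s} {r.ratio:6.3f} {r.vmlms_sub:6.3f} {r.tlms_sub:5d}")
print(f"\nVMLMs total: {score.vmlms_total:5.2f}   (truth {truth.vmlms_total:.2f})")
print(f"TLMs  total: {score.tlms_total:5d}   (truth {truth.tlms_total})")
print("the small VMLMs gap comes from intensity noise at cavity walls")
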