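"""Published reference-cohort summaries used for worked examples and
generator calibration.

Two summary tables from a 175-subject adult sinus-CT cohort (111 men,
64 women; 50 underwent endoscopic sinus surgery) are embedded here:

* ``COVARIATES`` / ``VOLUMES_ML`` — group means and standard deviations
  of the metrical characteristics and of each sinus cavity volume,
  overall and by sex.  These calibrate the synthetic cohort generator
  and provide the male/female ratio worked examples.
* ``SUBSCORES`` — mean per-region Lund-Mackay sub-scores (traditional
  0/1/2 grading, TLMs, and the volume-based continuous grading,
  VMLMs), stratified by surgical intervention.  Summing the twelve
  per-region means reproduces the printed totals (e.g. TLMs 14.9 in
  the surgical group), which is the score-aggregation worked example.

Values are stored exactly as printed, as (mean, sd) pairs.
"""

from __future__ import annotations

from .regions import REGION_IDS

# --- metrical characteristics: (mean, sd) for overall / male / female ---
COVARIATES: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"overall": (47.88, 15.81), "male": (46.19, 16.35), "female": (51.16, 14.31)},
    "height_cm": {"overall": (167.07, 8.93), "male": (171.06, 7.64), "female": (159.33, 5.54)},
    "weight_kg": {"overall": (66.70, 12.58), "male": (71.16, 11.10), "female": (58.06, 10.71)},
    "bmi": {"overall": (23.81, 3.63), "male": (24.30, 3.35), "female": (22.87, 3.98)},
}

MALE_FRACTION = 111 / 175
SURGERY_FRACTION = 50 / 175

# --- per-region cavity volumes in mL: (mean, sd) overall / male / female ---
VOLUMES_ML: dict[str, dict[str, tuple[float, float]]] = {
    "Max-L": {"overall": (14.26, 6.12), "male": (15.39, 6.27), "female": (11.88, 5.06)},
    "Max-R": {"overall": (14.39, 6.26), "male": (15.50, 6.45), "female": (12.04, 5.17)},
    "AE-L": {"overall": (1.49, 0.67), "male": (1.60, 0.72), "female": (1.28, 0.52)},
    "AE-R": {"overall": (1.49, 0.56), "male": (1.57, 0.57), "female": (1.34, 0.50)},
    "PE-L": {"overall": (1.35, 0.58), "male": (1.47, 0.57), "female": (1.13, 0.54)},
    "PE-R": {"overall": (1.40, 0.61), "male": (1.50, 0.61), "female": (1.21, 0.57)},
    "Fro-L": {"overall": (1.42, 1.24), "male": (1.68, 1.30), "female": (0.91, 0.92)},
    "Fro-R": {"overall": (1.34, 1.23), "male": (1.64, 1.33), "female": (0.77, 0.69)},
    "Sph-L": {"overall": (3.32, 2.00), "male": (3.64, 2.04), "female": (2.70, 1.77)},
    "Sph-R": {"overall": (3.43, 2.35), "male": (3.81, 2.47), "female": (2.70, 1.90)},
    # The OMC is scored but its cavity is small; no published volume —
    # a nominal 0.2 mL is used by the generator.
    "OMC-L": {"overall": (0.20, 0.08), "male": (0.21, 0.08), "female": (0.18, 0.07)},
    "OMC-R": {"overall": (0.20, 0.08), "male": (0.21, 0.08), "female": (0.18, 0.07)},
}

# --- mean per-region sub-scores (mean, sd), by score and surgery group ---
SUBSCORES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "tlms": {
        "surgery": {
            "Max-L": (1.36, 0.72), "Max-R": (1.56, 0.64),
            "AE-L": (1.70, 0.46), "AE-R": (1.64, 0.48),
            "PE-L": (1.26, 0.49), "PE-R": (1.22, 0.46),
            "Fro-L": (1.30, 0.54), "Fro-R": (1.34, 0.59),
            "Sph-L": (0.78, 0.65), "Sph-R": (0.66, 0.66),
            "OMC-L": (0.88, 1.00), "OMC-R": (1.20, 0.99),
        },
        "no_surgery": {
            "Max-L": (0.53, 0.67), "Max-R": (0.56, 0.66),
            "AE-L": (1.04, 0.20), "AE-R": (1.06, 0.25),
            "PE-L": (1.00, 0.29), "PE-R": (1.02, 0.21),
            "Fro-L": (0.67, 0.47), "Fro-R": (0.70, 0.50),
            "Sph-L": (0.21, 0.41), "Sph-R": (0.23, 0.43),
            "OMC-L": (0.19, 0.59), "OMC-R": (0.15, 0.53),
        },
    },
    "vmlms": {
        "surgery": {
            "Max-L": (1.11, 0.72), "Max-R": (1.32, 0.73),
            "AE-L": (1.32, 0.44), "AE-R": (1.33, 0.45),
            "PE-L": (0.85, 0.50), "PE-R": (0.77, 0.44),
            "Fro-L": (0.94, 0.69), "Fro-R": (1.02, 0.71),
            "Sph-L": (0.47, 0.52), "Sph-R": (0.44, 0.49),
            "OMC-L": (0.88, 2.01), "OMC-R": (1.20, 1.98),
        },
        "no_surgery": {
            "Max-L": (0.40, 0.50), "Max-R": (0.37, 0.46),
            "AE-L": (0.68, 0.19), "AE-R": (0.69, 0.23),
            "PE-L": (0.47, 0.25), "PE-R": (0.47, 0.21),
            "Fro-L": (0.27, 0.14), "Fro-R": (0.31, 0.21),
            "Sph-L": (0.17, 0.10), "Sph-R": (0.17, 0.08),
            "OMC-L": (0.19, 1.18), "OMC-R": (0.15, 1.06),
        },
    },
}

# Printed totals (mean, sd) for the same groups.
TOTALS: dict[str, dict[str, tuple[float, float]]] = {
    "tlms": {"surgery": (14.90, 3.66), "no_surgery": (7.38, 2.36)},
    "vmlms": {"surgery": (11.65, 4.23), "no_surgery": (4.34, 1.73)},
}


def subscore_means(score: str, group: str) -> dict[str, float]:
    """Mean sub-score per region for one score type and surgery group."""
    table = SUBSCORES[score][group]
    return {r: table[r][0] for r in REGION_IDS}


def mean_opacification(group: str) -> dict[str, float]:
    """Mean opacification ratio implied by the VMLMs sub-scores (sub/2)."""
    return {r: v / 2.0 for r, v in subscore_means("vmlms", group).items()}


def sex_volume_ratio(region_id: str) -> float:
    """Male/female ratio of mean cavity volume for one region."""
    male = VOLUMES_ML[region_id]["male"][0]
    female = VOLUMES_ML[region_id]["female"][0]
    return male / female
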