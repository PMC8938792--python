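"""Synthetic sinus-CT phantoms with exact ground truth.

A phantom is a head-CT-like voxel grid containing 12 disjoint labelled
cavities — ellipsoids standing in for the paired maxillary, anterior
and posterior ethmoid, frontal and sphenoid sinuses plus the two
ostiomeatal complexes — embedded in a bone shell within soft tissue.
Each cavity is partially filled with mucosa-intensity "disease" from
the cavity wall inward (the mucosal-thickening pattern), to a
controllable opacification fraction, with the realised fraction
voxel-exact up to quota rounding.  The generator is fully seeded:
identical spec and seed give bit-identical output.

``generate_cohort`` draws whole synthetic study populations whose
covariate–volume structure follows a published 175-subject reference
cohort: cavity volumes scale positively with body height, with a male
offset, surgical subjects carry higher opacification, and post-surgery
symptom scores drop for a configurable responder fraction whose
probability increases with continuous opacification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .grids import LabelMap, Volume
from .regions import REGION_IDS, region_class
from .volumetrics import RegionReport

__all__ = [
    "RegionGeometry",
    "PhantomSpec",
    "CohortModel",
    "CohortRecord",
    "generate_phantom",
    "generate_cohort",
    "reslice_coronal",
    "slices_to_arrays",
    "template_spec",
    "cohort_to_frame",
]


@dataclass(frozen=True)
class RegionGeometry:
    """One cavity: an ellipsoid (or box, for tests) in mm coordinates.

    ``center_mm``/``radii_mm`` are per-axis; for boxes the radii are
    half-widths.  ``opac_fraction`` is the requested fraction of cavity
    voxels filled with disease.
    """

    region_id: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    opac_fraction: float = 0.0
    shape: str = "ellipsoid"

    def __post_init__(self):
        region_class(self.region_id)  # validates the id
        if not 0.0 <= self.opac_fraction <= 1.0:
            raise ValueError(
                f"{self.region_id}: opac_fraction must be in [0,1], "
                f"got {self.opac_fraction}")
        if self.shape not in ("ellipsoid", "box"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"{self.region_id}: radii must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one phantom volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    regions: tuple[RegionGeometry, ...] = ()
    noise_sd: float = 15.0
    hu_air: float = -1000.0
    hu_mucosa: float = 40.0
    hu_bone: float = 700.0
    hu_background: float = 0.0
    shell_voxels: int = 2
    orientation: str = "RAS"
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(g < 16 for g in self.grid_shape):
            raise ValueError("grid_shape must be three extents, all >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not (self.hu_air < self.hu_mucosa < self.hu_bone):
            raise ValueError("need hu_air < hu_mucosa < hu_bone")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "regions", tuple(self.regions))


def _voxel_centers(grid_shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _region_mask(geom: RegionGeometry, coords) -> np.ndarray:
    cx, cy, cz = coords
    if geom.shape == "box":
        return ((np.abs(cx - geom.center_mm[0]) < geom.radii_mm[0])
                & (np.abs(cy - geom.center_mm[1]) < geom.radii_mm[1])
                & (np.abs(cz - geom.center_mm[2]) < geom.radii_mm[2]))
    d = ((cx - geom.center_mm[0]) / geom.radii_mm[0]) ** 2 \
        + ((cy - geom.center_mm[1]) / geom.radii_mm[1]) ** 2 \
        + ((cz - geom.center_mm[2]) / geom.radii_mm[2]) ** 2
    return d < 1.0


def _opacify(mask: np.ndarray, fraction: float, spacing) -> np.ndarray:
    """Select the disease voxels of one cavity, wall inward.

    The quota round(fraction * n) of voxels closest to the cavity wall
    (smallest Euclidean distance to the outside) is filled; ties break
    by distance then lexicographic voxel index, so the result is
    deterministic.
    """
    n = int(mask.sum())
    quota = int(round(fraction * n))
    disease = np.zeros_like(mask)
    if quota == 0:
        return disease
    if quota >= n:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    flat_idx = np.flatnonzero(mask.ravel())
    d = dist.ravel()[flat_idx]
    order = np.lexsort((flat_idx, d))
    chosen = flat_idx[order[:quota]]
    disease.ravel()[chosen] = True
    return disease


def _find_overlap_pair(masks: dict[str, np.ndarray]) -> tuple[str, str]:
    ids = list(masks)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if np.any(masks[a] & masks[b]):
                return a, b
    raise AssertionError("overlap detected but no colliding pair found")


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(volume, labelmap, ground_truth)`` where ``ground_truth``
    is a list of :class:`~sinusvol.volumetrics.RegionReport` with exact
    voxel-counted volumes and opacification ratios.  Overlapping region
    geometries are rejected with a diagnostic naming the colliding
    pair.
    """
    coords = _voxel_centers(spec.grid_shape, spec.spacing_mm)
    masks = {g.region_id: _region_mask(g, coords) for g in spec.regions}
    occupancy = np.zeros(spec.grid_shape, dtype=np.int8)
    for m in masks.values():
        occupancy += m
    if occupancy.max() > 1:
        a, b = _find_overlap_pair(masks)
        raise ValueError(f"region geometries overlap: {a} collides with {b}")

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    intensity = np.full(spec.grid_shape, spec.hu_background, dtype=np.float32)
    cavity_all = occupancy > 0
    shell = ndimage.binary_dilation(cavity_all, iterations=spec.shell_voxels)
    intensity[shell & ~cavity_all] = spec.hu_bone

    vox_ml = float(np.prod(spec.spacing_mm)) / 1000.0
    ground_truth: list[RegionReport] = []
    for geom in spec.regions:
        mask = masks[geom.region_id]
        labels[mask] = region_class(geom.region_id)
        disease = _opacify(mask, geom.opac_fraction, spec.spacing_mm)
        intensity[mask] = spec.hu_air
        intensity[disease] = spec.hu_mucosa
        n = int(mask.sum())
        n_dis = int(disease.sum())
        ground_truth.append(RegionReport.from_counts(
            geom.region_id, n - n_dis, n_dis, vox_ml))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, spec.noise_sd, spec.grid_shape).astype(np.float32)
    volume = Volume(intensity.astype(np.float32), spec.spacing_mm, spec.orientation)
    labelmap = LabelMap(labels, spec.spacing_mm, spec.orientation)
    return volume, labelmap, ground_truth


# --------------------------------------------------------------------------
# Template anatomy: per-region allocation boxes in fractional coordinates.
# Boxes are pairwise disjoint by construction (separated along y or z, with
# left/right mirrored about x = 0.5), so ellipsoids capped to stay strictly
# inside their box can never collide, whatever the drawn volumes.
# Axis order: x = right(+), y = anterior(+), z = superior(+) ("RAS").

_TEMPLATE_LEFT: dict[str, dict] = {
    "Max-L": {"box": ((0.03, 0.47), (0.36, 0.90), (0.05, 0.50)),
              "aspect": (1.0, 1.15, 0.85)},
    "Sph-L": {"box": ((0.28, 0.50), (0.05, 0.36), (0.05, 0.50)),
              "aspect": (0.9, 1.1, 1.0)},
    "AE-L": {"box": ((0.28, 0.50), (0.52, 0.72), (0.50, 0.74)),
             "aspect": (1.0, 1.0, 1.0)},
    "PE-L": {"box": ((0.28, 0.50), (0.28, 0.52), (0.50, 0.74)),
             "aspect": (1.0, 1.0, 1.0)},
    "OMC-L": {"box": ((0.28, 0.50), (0.72, 0.92), (0.50, 0.74)),
              "aspect": (1.0, 1.0, 1.0)},
    "Fro-L": {"box": ((0.25, 0.50), (0.45, 0.90), (0.74, 0.96)),
              "aspect": (1.1, 1.1, 0.8)},
}


def _template_entry(region_id: str) -> dict:
    if region_id.endswith("-L"):
        return _TEMPLATE_LEFT[region_id]
    left = _TEMPLATE_LEFT[region_id[:-2] + "-L"]
    (x0, x1), ybox, zbox = left["box"]
    return {"box": ((1.0 - x1, 1.0 - x0), ybox, zbox), "aspect": left["aspect"]}


def template_spec(
    volumes_ml: dict[str, float],
    opac_fractions: dict[str, float],
    grid_shape=(48, 48, 40),
    spacing_mm=(2.0, 2.0, 2.0),
    noise_sd: float = 15.0,
    seed: int = 0,
    jitter_frac: float = 0.05,
    rng: np.random.Generator | None = None,
) -> PhantomSpec:
    """Build a PhantomSpec realising target cavity volumes on the
    template anatomy.

    Ellipsoid radii are sized from the requested volume and capped to
    the region's allocation box (minus jitter), so regions are always
    disjoint; very large draws are realised slightly smaller than
    requested.
    """
    rng = rng or np.random.default_rng(seed)
    extent = np.array(grid_shape, dtype=float) * np.array(spacing_mm, dtype=float)
    regions = []
    for rid in REGION_IDS:
        entry = _template_entry(rid)
        box = np.array(entry["box"], dtype=float)  # (3, 2) fractions
        aspect = np.array(entry["aspect"], dtype=float)
        hw = (box[:, 1] - box[:, 0]) / 2.0 * extent
        center = (box[:, 0] + box[:, 1]) / 2.0 * extent
        jitter = rng.uniform(-jitter_frac, jitter_frac, 3) * 2.0 * hw
        center = center + jitter
        target = max(float(volumes_ml.get(rid, 0.2)), 0.02) * 1000.0  # mm^3
        aspect = aspect / np.cbrt(np.prod(aspect))
        r_eff = np.cbrt(3.0 * target / (4.0 * np.pi))
        radii = aspect * r_eff
        cap = 0.95 * (hw - np.abs(jitter))
        radii = np.minimum(radii, cap)
        radii = np.maximum(radii, 1.2 * np.asarray(spacing_mm))
        regions.append(RegionGeometry(
            rid, tuple(center), tuple(radii),
            opac_fraction=float(opac_fractions.get(rid, 0.0))))
    return PhantomSpec(
        grid_shape=tuple(grid_shape), spacing_mm=tuple(spacing_mm),
        regions=tuple(regions), noise_sd=noise_sd,
        seed=int(rng.integers(2**31 - 1)))


# --------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortModel:
    """Parameters of the synthetic study population.

    Defaults reproduce the reference cohort's structure: sex mix and
    covariate means/SDs from the published table, cavity volumes linear
    in body height with a direct male offset (group means match the
    printed male/female means in expectation), surgical subjects drawn
    with higher opacification (group mean ratios follow the published
    per-region sub-scores), and a responder fraction whose probability
    increases with continuous opacification.
    """

    male_fraction: float = reference.MALE_FRACTION
    surgery_fraction: float = reference.SURGERY_FRACTION
    #: scales the height coefficient; 0 removes the height effect
    #: (the male/female mean difference is then carried entirely by the
    #: direct sex offset, keeping group means unchanged).
    height_coef_scale: float = 1.0
    #: share of the male-female mean difference carried by a direct sex
    #: offset rather than mediated through height.
    sex_direct_fraction: float = 0.3
    volume_noise_scale: float = 0.8
    opac_concentration: float = 8.0
    #: SD of the subject-level disease-severity latent (logit scale);
    #: shifts every region's opacification together, giving the
    #: correlated multi-sinus involvement seen in CRS.
    severity_sd: float = 1.0
    responder_fraction: float = 0.6
    responder_coupling: float = 2.5
    grid_shape: tuple[int, int, int] = (48, 48, 40)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sd: float = 15.0
    jitter_frac: float = 0.05

    def height_coef(self, region_id: str) -> float:
        """mL of cavity volume per cm of body height for one region."""
        male = reference.VOLUMES_ML[region_id]["male"][0]
        female = reference.VOLUMES_ML[region_id]["female"][0]
        h_m = reference.COVARIATES["height_cm"]["male"][0]
        h_f = reference.COVARIATES["height_cm"]["female"][0]
        return (self.height_coef_scale * (1.0 - self.sex_direct_fraction)
                * (male - female) / (h_m - h_f))


@dataclass(frozen=True)
class CohortRecord:
    """Covariates and generative ground truth for one synthetic subject."""

    subject_id: str
    age: float
    sex: str
    height_cm: float
    weight_kg: float
    surgery: bool
    snot22_pre: float
    snot22_post: float
    responder: bool
    volumes_ml: dict[str, float]
    opac_fractions: dict[str, float]

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        for v in (self.snot22_pre, self.snot22_post):
            if not 0.0 <= v <= 110.0:
                raise ValueError("SNOT-22 scores must be within 0-110")
        if any(v <= 0 for v in self.volumes_ml.values()):
            raise ValueError("cavity volumes must be positive")


def _draw_volume(model: CohortModel, rid: str, male: bool, height: float,
                 rng: np.random.Generator) -> float:
    ref = reference.VOLUMES_ML[rid]
    f_mean, sd = ref["female"][0], ref["overall"][1]
    m_mean = ref["male"][0]
    h_m = reference.COVARIATES["height_cm"]["male"][0]
    h_f = reference.COVARIATES["height_cm"]["female"][0]
    h_bar = reference.COVARIATES["height_cm"]["overall"][0]
    b = model.height_coef(rid)
    offset = (m_mean - f_mean) - b * (h_m - h_f)
    a = f_mean - b * (h_f - h_bar)
    v = a + (offset if male else 0.0) + b * (height - h_bar) \
        + rng.normal(0.0, model.volume_noise_scale * sd)
    return float(max(v, 0.1 * f_mean))


def generate_cohort(n: int, covariate_model: CohortModel | None = None,
                    seed: int = 0) -> list[tuple[CohortRecord, PhantomSpec]]:
    """Draw ``n`` synthetic subjects with matching phantom specs."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    model = covariate_model or CohortModel()
    rng = np.random.default_rng(seed)
    cov = reference.COVARIATES
    opac_means = {g: reference.mean_opacification(
        "surgery" if g else "no_surgery") for g in (True, False)}
    mean_surgery_ratio = float(np.mean(list(opac_means[True].values())))

    out: list[tuple[CohortRecord, PhantomSpec]] = []
    for i in range(n):
        male = rng.random() < model.male_fraction
        grp = "male" if male else "female"
        height = rng.normal(*cov["height_cm"][grp])
        age = float(np.clip(rng.normal(*cov["age"][grp]), 21, 80))
        weight = (cov["weight_kg"][grp][0]
                  + 0.55 * (height - cov["height_cm"][grp][0])
                  + rng.normal(0.0, 0.8 * cov["weight_kg"][grp][1]))
        surgery = rng.random() < model.surgery_fraction
        volumes = {rid: _draw_volume(model, rid, male, height, rng)
                   for rid in REGION_IDS}
        kappa = model.opac_concentration
        severity = rng.normal(0.0, model.severity_sd)
        opac = {}
        for rid in REGION_IDS:
            mu = float(np.clip(opac_means[surgery][rid], 0.02, 0.95))
            mu = float(1.0 / (1.0 + np.exp(-(np.log(mu / (1 - mu)) + severity))))
            mu = float(np.clip(mu, 0.02, 0.98))
            opac[rid] = float(rng.beta(mu * kappa, (1.0 - mu) * kappa))
        mean_ratio = float(np.mean(list(opac.values())))
        pre = float(np.clip(18.0 + 55.0 * mean_ratio + rng.normal(0, 6.0),
                            1.0, 110.0))
        if surgery:
            p_resp = float(np.clip(
                model.responder_fraction
                + model.responder_coupling * (mean_ratio - mean_surgery_ratio),
                0.05, 0.95))
            responder = rng.random() < p_resp
            reduction = rng.uniform(0.30, 0.60) if responder \
                else rng.uniform(0.0, 0.20)
        else:
            responder = False
            reduction = rng.uniform(0.0, 0.10)
        post = float(np.clip(pre * (1.0 - reduction), 0.0, 110.0))
        record = CohortRecord(
            subject_id=f"S{i:04d}", age=age, sex="M" if male else "F",
            height_cm=float(height), weight_kg=float(weight),
            surgery=bool(surgery), snot22_pre=pre, snot22_post=post,
            responder=bool(responder), volumes_ml=volumes,
            opac_fractions=opac)
        spec = template_spec(
            volumes, opac, grid_shape=model.grid_shape,
            spacing_mm=model.spacing_mm, noise_sd=model.noise_sd,
            jitter_frac=model.jitter_frac, rng=rng)
        out.append((record, spec))
    return out


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "age": r.age, "sex": r.sex,
            "height_cm": r.height_cm, "weight_kg": r.weight_kg,
            "surgery": r.surgery, "snot22_pre": r.snot22_pre,
            "snot22_post": r.snot22_post, "responder": r.responder,
        }
        for rid in REGION_IDS:
            row[f"vol_{rid}"] = r.volumes_ml[rid]
            row[f"opac_{rid}"] = r.opac_fractions[rid]
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Reslicing and training arrays


def reslice_coronal(volume: Volume, labelmap: LabelMap | None = None):
    """Split a volume into ordered coronal (anteroposterior) slices.

    Returns ``(slices, label_slices)``; ``label_slices`` is None when no
    label map is given.  Stacking the slices along the same axis
    reconstructs the volume bit-exactly.
    """
    axis = volume.coronal_axis  # raises if the orientation tag is absent
    n = volume.shape[axis]
    slices = [np.take(volume.data, j, axis=axis) for j in range(n)]
    label_slices = None
    if labelmap is not None:
        if labelmap.shape != volume.shape:
            raise ValueError("label map misaligned with volume")
        label_slices = [np.take(labelmap.data, j, axis=axis) for j in range(n)]
    return slices, label_slices


def slices_to_arrays(volume: Volume, labelmap: LabelMap | None = None,
                     slice_step: int = 1, hu_scale: float = 1000.0):
    """Coronal slices as network inputs: (N, 4, H, W) float32.

    Channels: intensity / ``hu_scale``, then three normalised
    coordinate ramps (row, column, slice position) that let the network
    distinguish structures of identical density by location.
    """
    slices, label_slices = reslice_coronal(volume, labelmap)
    n_total = len(slices)
    idx = range(0, n_total, slice_step)
    h, w = slices[0].shape
    rr, cc = np.meshgrid(np.linspace(0, 1, h, dtype=np.float32),
                         np.linspace(0, 1, w, dtype=np.float32), indexing="ij")
    xs, ys = [], []
    for j in idx:
        pos = np.full((h, w), j / max(n_total - 1, 1), dtype=np.float32)
        xs.append(np.stack([slices[j].astype(np.float32) / hu_scale,
                            rr, cc, pos]))
        if label_slices is not None:
            ys.append(label_slices[j].astype(np.int64))
    x = np.stack(xs)
    y = np.stack(ys) if ys else None
    return x, y
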