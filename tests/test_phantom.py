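"""Phantom generator: exact ground truth, determinism, opacification
realisation, reslicing round-trips, and cohort covariate structure."""

import numpy as np
import pytest
from scipy import stats

from sinusvol.phantom import (
    CohortModel,
    PhantomSpec,
    RegionGeometry,
    cohort_to_frame,
    generate_cohort,
    generate_phantom,
    reslice_coronal,
    slices_to_arrays,
)
from sinusvol.regions import REGION_IDS, region_class


class TestGeneratePhantom:
    def test_cubic_region_volume_and_ratio(self, cube_spec):
        """A 10^3-voxel cube at 1 mm spacing is exactly 1 mL, all air."""
        vol, lm, gt = generate_phantom(cube_spec)
        (report,) = gt
        assert report.total_ml == pytest.approx(1.0)
        assert report.ratio == 0.0
        assert (lm.data == region_class("Max-L")).sum() == 1000

    def test_fully_opacified_everywhere(self, default_phantom):
        record, spec, *_ = default_phantom
        import dataclasses

        full = dataclasses.replace(
            spec, regions=tuple(dataclasses.replace(g, opac_fraction=1.0)
                                for g in spec.regions))
        _, _, gt = generate_phantom(full)
        assert all(r.ratio == 1.0 for r in gt)

    def test_opacification_fraction_realised_exactly(self):
        """Requested fraction is realised to quota rounding, verified by
        brute-force voxel enumeration."""
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            regions=(RegionGeometry("Sph-L", (16, 16, 16), (10, 9, 11),
                                    opac_fraction=0.37),),
            noise_sd=0.0, seed=1)
        vol, lm, gt = generate_phantom(spec)
        (report,) = gt
        # oracle: enumerate cavity voxels and count disease by intensity
        mask = lm.data == region_class("Sph-L")
        n = int(mask.sum())
        n_disease = int((vol.data[mask] > -400).sum())
        assert n > 3000
        assert report.ratio == pytest.approx(n_disease / n)
        assert report.ratio == pytest.approx(round(0.37 * n) / n)
        assert abs(report.ratio - 0.37) < 1.0 / np.cbrt(n)  # one-shell slack

    def test_disease_fills_from_wall_inward(self):
        from scipy import ndimage

        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            regions=(RegionGeometry("Max-L", (16, 16, 16), (11, 11, 11),
                                    opac_fraction=0.4),),
            noise_sd=0.0, seed=1)
        vol, lm, _ = generate_phantom(spec)
        mask = lm.data == region_class("Max-L")
        disease = mask & (vol.data > -400)
        air = mask & ~disease
        dist = ndimage.distance_transform_edt(mask)
        assert dist[disease].mean() < dist[air].mean()

    def test_deterministic_under_seed(self, default_phantom):
        record, spec, vol, lm, gt = default_phantom
        vol2, lm2, gt2 = generate_phantom(spec)
        assert np.array_equal(vol.data, vol2.data)
        assert np.array_equal(lm.data, lm2.data)
        assert gt == gt2

    def test_overlap_rejected_with_pair_diagnostic(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            regions=(RegionGeometry("Max-L", (14, 16, 16), (6, 6, 6)),
                     RegionGeometry("Max-R", (18, 16, 16), (6, 6, 6))))
        with pytest.raises(ValueError, match="Max-L.*Max-R"):
            generate_phantom(spec)

    def test_conservation_and_ratio_consistency(self, default_phantom):
        """Label-map voxel counts equal air+disease counts; ratio is
        disease/(air+disease) exactly."""
        record, spec, vol, lm, gt = default_phantom
        vox_ml = lm.voxel_volume_ml
        for r in gt:
            n_label = int((lm.data == region_class(r.region_id)).sum())
            n_air = round(r.air_ml / vox_ml)
            n_dis = round(r.disease_ml / vox_ml)
            assert n_air + n_dis == n_label
            expect = n_dis / n_label if n_label else 0.0
            assert r.ratio == pytest.approx(expect, abs=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="grid_shape"):
            PhantomSpec(grid_shape=(8, 32, 32))
        with pytest.raises(ValueError, match="hu_air"):
            PhantomSpec(hu_air=100.0, hu_mucosa=40.0)
        with pytest.raises(ValueError, match="opac_fraction"):
            RegionGeometry("Max-L", (0, 0, 0), (5, 5, 5), opac_fraction=1.5)


class TestResliceCoronal:
    def test_slice_count_equals_anteroposterior_extent(self, default_phantom):
        *_, vol, lm, gt = default_phantom
        slices, lslices = reslice_coronal(vol, lm)
        assert len(slices) == vol.shape[vol.coronal_axis]

    def test_round_trip_is_bit_exact(self, default_phantom):
        *_, vol, lm, gt = default_phantom
        slices, lslices = reslice_coronal(vol, lm)
        axis = vol.coronal_axis
        assert np.array_equal(np.stack(slices, axis=axis), vol.data)
        assert np.array_equal(np.stack(lslices, axis=axis), lm.data)

    def test_slice_histograms_match_volume_planes(self, default_phantom):
        *_, vol, lm, gt = default_phantom
        _, lslices = reslice_coronal(vol, lm)
        axis = vol.coronal_axis
        for k in (0, 10, 20):
            plane = np.take(lm.data, k, axis=axis)
            assert np.array_equal(np.bincount(lslices[k].ravel(), minlength=13),
                                  np.bincount(plane.ravel(), minlength=13))

    def test_missing_orientation_rejected(self, default_phantom):
        import dataclasses

        *_, vol, lm, gt = default_phantom
        bad = dataclasses.replace(vol, orientation=None) if False else None
        from sinusvol.grids import Volume

        v = Volume(vol.data, vol.spacing_mm, None)
        with pytest.raises(ValueError, match="orientation"):
            reslice_coronal(v)

    def test_training_arrays_have_coordinate_channels(self, default_phantom):
        *_, vol, lm, gt = default_phantom
        x, y = slices_to_arrays(vol, lm, slice_step=2)
        assert x.shape[1] == 4 and x.dtype == np.float32
        assert y.shape == (x.shape[0], x.shape[2], x.shape[3])
        assert x[0, 1].min() == 0.0 and x[0, 1].max() == 1.0  # row ramp
        assert np.unique(x[:, 3]).size == x.shape[0]  # slice position


class TestGenerateCohort:
    def test_empty_cohort_refused(self):
        with pytest.raises(ValueError):
            generate_cohort(0)

    def test_deterministic(self):
        a = generate_cohort(3, seed=9)
        b = generate_cohort(3, seed=9)
        assert cohort_to_frame([r for r, _ in a]).equals(
            cohort_to_frame([r for r, _ in b]))

    @pytest.fixture(scope="class")
    def cohort200(self):
        return cohort_to_frame([r for r, _ in generate_cohort(200, seed=11)])

    def test_sex_dimorphism_in_maxillary_volume(self, cohort200):
        """Male mean Max-L volume exceeds female, and a two-sample test
        rejects at the 5% level."""
        df = cohort200
        male = df[df.sex == "M"]["vol_Max-L"]
        female = df[df.sex == "F"]["vol_Max-L"]
        assert male.mean() > female.mean()
        total_m = df[df.sex == "M"].filter(like="vol_").sum(axis=1)
        total_f = df[df.sex == "F"].filter(like="vol_").sum(axis=1)
        assert stats.ttest_ind(total_m, total_f, equal_var=False).pvalue < 0.05

    def test_surgery_group_more_opacified(self, cohort200):
        df = cohort200
        opac = df.filter(like="opac_").mean(axis=1)
        assert opac[df.surgery].mean() > opac[~df.surgery].mean() + 0.1

    def test_height_volume_correlation_positive(self, cohort200):
        df = cohort200
        total = df.filter(like="vol_").sum(axis=1)
        r, p = stats.pearsonr(df.height_cm, total)
        assert r > 0 and p < 0.01

    def test_phantom_specs_realise_without_overlap(self):
        # largest plausible volumes must still render disjoint regions
        for rec, spec in generate_cohort(4, seed=33):
            vol, lm, gt = generate_phantom(spec)
            realised = {r.region_id: r.total_ml for r in gt}
            for rid in REGION_IDS:
                assert realised[rid] > 0
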