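import numpy as np
import pytest

from sinusvol.phantom import (
    PhantomSpec,
    RegionGeometry,
    generate_cohort,
    generate_phantom,
    slices_to_arrays,
)


@pytest.fixture(scope="session")
def cube_spec():
    """One 10x10x10-voxel cubic test region at 1 mm spacing."""
    return PhantomSpec(
        grid_shape=(24, 24, 24), spacing_mm=(1.0, 1.0, 1.0),
        regions=(RegionGeometry("Max-L", center_mm=(12.0, 12.0, 12.0),
                                radii_mm=(5.0, 5.0, 5.0), shape="box"),),
        noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def default_phantom():
    """A full 12-region phantom drawn from the default cohort model."""
    record, spec = generate_cohort(1, seed=42)[0]
    vol, lm, gt = generate_phantom(spec)
    return record, spec, vol, lm, gt


@pytest.fixture(scope="session")
def phantom_dataset():
    """Eight phantoms with slice arrays, for training-related tests."""
    cohort = generate_cohort(8, seed=21)
    data = {}
    truth = {}
    for rec, spec in cohort:
        vol, lm, gt = generate_phantom(spec)
        data[rec.subject_id] = slices_to_arrays(vol, lm, slice_step=2)
        truth[rec.subject_id] = (vol, lm, gt)
    return data, truth
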