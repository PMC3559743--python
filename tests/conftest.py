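import numpy as np
import pytest

from brainprint import PhantomConfig, build_dataset, smooth_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast phantom cohort: 5 subjects, 2 visits x 3 scans, 16^3 grid."""
    return PhantomConfig(
        grid_shape=(16, 16, 16),
        n_subjects=5,
        visits_per_subject=2,
        scans_per_visit=3,
        master_seed=123,
    )


@pytest.fixture(scope="session")
def small_index(small_config):
    return build_dataset(small_config)


@pytest.fixture(scope="session")
def default_experiment_index():
    """The default-scale phantom cohort (150 subjects, 2 visits x 3 scans,
    32^3 grid) smoothed at the default 8 mm FWHM — the dataset on which the
    headline verification and identification analogs are evaluated."""
    return smooth_dataset(build_dataset(PhantomConfig()), 8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_volume(data, subject="S", visit=1, scan=1, voxel=(1.0, 1.0, 1.0)):
    from brainprint import GMVolume

    return GMVolume(
        subject_id=subject,
        visit_id=visit,
        scan_id=scan,
        data=np.asarray(data, dtype=np.float32),
        voxel_size_mm=voxel,
    )
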