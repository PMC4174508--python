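import numpy as np
import pytest

from pvi_scarpipe.core import ImageVolume, make_affine
from pvi_scarpipe.phantom import PhantomSpec, generate_phantom
from pvi_scarpipe.pipeline import RunConfig, run_pipeline

COHORT_SEED = 0


@pytest.fixture(scope="session")
def cohort_results():
    """Full 7-subject phantom pipeline run used by the acceptance tests."""
    return run_pipeline(RunConfig(seed=COHORT_SEED, n_subjects=7))


@pytest.fixture(scope="session")
def default_phantom():
    """One noisy phantom subject with the default injury pattern."""
    spec = PhantomSpec(rng_seed=42, subject_id="fixture")
    volumes, truth = generate_phantom(spec)
    return spec, volumes, truth


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Phantom with all cohort-draw and voxel-noise SDs at zero."""
    spec = PhantomSpec(rng_seed=42, subject_id="noise-free")
    spec = PhantomSpec(rng_seed=42, subject_id="noise-free",
                       signal_params=spec.signal_params.noise_free())
    volumes, truth = generate_phantom(spec)
    return spec, volumes, truth


def make_volume(data, spacing=(1.0, 1.0, 1.0), **tags):
    return ImageVolume(np.asarray(data, dtype=float), make_affine(spacing),
                       **tags)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
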