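import numpy as np
import pytest

from thyrocad.io import Manifest, load_manifest
from thyrocad.phantom import PhantomParams, generate_cohort
from thyrocad.preprocess import make_sample


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    """A small, fast phantom configuration used by most integration tests."""
    return PhantomParams(
        n_malignant=2,
        n_benign=3,
        grid_shape=(32, 32, 16),
        nodule_radius_range=(4.0, 7.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory, tiny_params) -> Manifest:
    out = tmp_path_factory.mktemp("tiny_cohort")
    generate_cohort(tiny_params, out)
    return load_manifest(out / "manifest.csv")


@pytest.fixture(scope="session")
def tiny_samples(tiny_cohort):
    return [make_sample(case) for case in tiny_cohort]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
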