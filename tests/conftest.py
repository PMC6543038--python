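import numpy as np
import pytest

from scentstress.config import RoiParams, SyntheticConfig, default_coupled_edges


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down cohort for fast plumbing tests (not a power analysis)."""
    return SyntheticConfig(
        n_control=4,
        n_exposed=12,
        seed=7,
        roi=RoiParams(
            n_regions=12,
            n_volumes=400,
            coupled_edges=default_coupled_edges(12, 3, 0.5),
        ),
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    from scentstress.io import generate_dataset

    outdir = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(small_config, outdir)
    return outdir, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
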