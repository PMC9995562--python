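import numpy as np
import pytest

from eventrsa import (
    GeneratorConfig,
    build_all_model_matrices,
    build_default_design,
    generate_dataset,
)


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def models(design):
    return build_all_model_matrices(design)


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap multi-subject dataset shared by pipeline-level tests."""
    cfg = GeneratorConfig(n_subjects=6, n_voxels=60, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
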