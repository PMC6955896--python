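import numpy as np
import pytest

from somabci import (GeneratorConfig, PipelineBundle, build_electrode_array,
                     build_head_model, build_roi_atlas, build_source_space,
                     compute_inverse_operator, compute_lead_field,
                     generate_trialset)


@pytest.fixture(scope="session")
def head_model():
    return build_head_model()


@pytest.fixture(scope="session")
def atlas():
    return build_roi_atlas()


@pytest.fixture(scope="session")
def electrodes(head_model):
    return build_electrode_array(32, head_model)


@pytest.fixture(scope="session")
def source_space(head_model, atlas):
    return build_source_space(600, head_model, atlas, seed=0)


@pytest.fixture(scope="session")
def lead_field(electrodes, source_space, head_model):
    return compute_lead_field(electrodes, source_space, head_model)


@pytest.fixture(scope="session")
def inverse_op(lead_field):
    return compute_inverse_operator(lead_field)


@pytest.fixture(scope="session")
def small_splits(lead_field, source_space):
    """Modest synthetic train/test splits for unit tests (default effects)."""
    config = GeneratorConfig(n_train=60, n_test=40, seed=7)
    return generate_trialset(config, lead_field, source_space)


@pytest.fixture(scope="session")
def bundle(small_splits, inverse_op, source_space):
    train, test = small_splits
    return PipelineBundle(train, test, inverse_op, source_space)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
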