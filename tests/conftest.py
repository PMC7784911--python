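import numpy as np
import pytest

from bbbmap import (
    PhantomSpec,
    PipelineConfig,
    generate_phantom,
    run_subject_arrays,
)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default-geometry phantom with no noise (160 dynamics, 20x20x8)."""
    return generate_phantom(PhantomSpec(noise_model="none", seed=7))


@pytest.fixture(scope="session")
def phantom_chain(noiseless_phantom):
    """Full subject-level chain run on the noiseless phantom."""
    ds = noiseless_phantom
    res = run_subject_arrays(
        ds.as_vfa_stack(),
        ds.as_b1_map(),
        ds.as_dynamic_series(),
        ds.brain_mask,
        ds.vif_mask,
        PipelineConfig(),
    )
    return ds, res


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
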