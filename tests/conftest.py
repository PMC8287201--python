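import numpy as np
import pytest

from netarget.phantom import PhantomSpec, generate_phantom
from netarget.pipeline import run_phantom_pipeline


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_phantom(PhantomSpec(noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate_phantom(PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def pipeline_seed1():
    """Full pipeline run on the default phantom, reused across tests."""
    return run_phantom_pipeline(seed=1)


@pytest.fixture(scope="session")
def ad_table():
    from netarget.tables import load_target_table

    return load_target_table("ad")


@pytest.fixture(scope="session")
def hc_table():
    from netarget.tables import load_target_table

    return load_target_table("hc")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
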