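import numpy as np
import pytest

from hemaseg.synthdata import PhantomSpec, generate_phantom_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest phantom cohort shared by read-only tests."""
    spec = PhantomSpec(n_scans=8, slices_per_scan=(3, 5), seed=42)
    return generate_phantom_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model():
    from hemaseg.model import build_model

    return build_model("tiny", adapter_m=8, seed=7)
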