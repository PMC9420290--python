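import numpy as np
import pytest

from afdetect import IegmRecord, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noise_record(rng):
    """2 s of seeded Gaussian noise at 1 kHz."""
    return IegmRecord("noise", rng.standard_normal(2000), fs=1000.0)


@pytest.fixture
def clean_biphasic_record():
    """One noise-free biphasic record with known truth."""
    cfg = SynthConfig(
        duration_s=10.0,
        mean_cl=200.0,
        noise_sd=0.0,
        morphology_mix={"biphasic": 1.0, "fractionated": 0.0, "double_peak": 0.0},
        seed=3,
    )
    return generate(cfg)
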