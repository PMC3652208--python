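import numpy as np
import pytest

from ecgmmc.synthetic import gen_synthetic_ecg


def pearson(a, b):
    return float(np.corrcoef(np.asarray(a), np.asarray(b))[0, 1])


@pytest.fixture(scope="session")
def clean_ecg():
    """12 s clean normal-rhythm record at 360 Hz with ground truth."""
    return gen_synthetic_ecg(fs=360, duration=12, seed=3)
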