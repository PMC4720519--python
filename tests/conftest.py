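import numpy as np
import pytest

from caosc.config import AcquisitionConfig
from caosc.synthgen import SpikeTrain


@pytest.fixture
def acq_600s() -> AcquisitionConfig:
    return AcquisitionConfig(duration_s=600.0)


@pytest.fixture
def acq_1000s() -> AcquisitionConfig:
    return AcquisitionConfig(duration_s=1000.0)


@pytest.fixture
def empty_train() -> SpikeTrain:
    return SpikeTrain(np.empty(0), np.empty(0), np.empty(0), np.empty(0))


def make_train(times, amps=None, rises=None, decays=None) -> SpikeTrain:
    times = np.asarray(times, dtype=float)
    n = len(times)
    return SpikeTrain(
        times,
        np.full(n, 1.0) if amps is None else np.asarray(amps, dtype=float),
        np.full(n, 10.0) if rises is None else np.asarray(rises, dtype=float),
        np.full(n, 8.0) if decays is None else np.asarray(decays, dtype=float),
    )
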