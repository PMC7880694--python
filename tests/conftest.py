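import numpy as np
import pytest

from aslkit import AcquisitionParams, TissueParams


@pytest.fixture
def acq() -> AcquisitionParams:
    return AcquisitionParams()  # τ=3000 ms, PLD=300 ms, T1b=2230 ms, λ=0.9, α=0.9


@pytest.fixture
def tissue() -> TissueParams:
    return TissueParams(t1_tissue=1700.0, m0_tissue=1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)
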