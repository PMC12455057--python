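import numpy as np
import pytest

from ratbold import synth
from ratbold.design import Block, Paradigm, ScanMeta


@pytest.fixture(scope="session")
def small_cfg():
    """A small, fast synthetic scene shared across tests."""
    return synth.SynthConfig(
        n_subjects=4,
        grid=(12, 12, 6),
        n_vols=120,
        paradigm=Paradigm(blocks=(Block(40.0, 20.0), Block(100.0, 20.0))),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synth.generate_cohort(small_cfg)


@pytest.fixture
def meta():
    return ScanMeta(tr=2.0, n_vols=150)


@pytest.fixture
def paradigm():
    return synth.default_paradigm()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
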