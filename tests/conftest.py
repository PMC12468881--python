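import numpy as np
import pytest

from lncatlas.simulate import SimConfig, simulate_truth


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: 5 tissues x 4 samples, 2000 lncRNAs,
    200 planted housekeeping, 300 planted tissue-specific, 10% conserved,
    seed 42."""
    cfg = SimConfig()
    ann, cm, truth, aux = simulate_truth(cfg)
    return cfg, ann, cm, truth, aux


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
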