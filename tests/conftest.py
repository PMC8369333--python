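import numpy as np
import pytest

from bayesequiv import CauchyPrior, EquivalenceRegion, TwoSampleSummary, pooled_t


@pytest.fixture(scope="session")
def moderate_summary():
    """A moderately informative two-sample summary (t about 2)."""
    return TwoSampleSummary(n1=30, n2=30, mean1=0.5, mean2=0.0, sd1=1.0, sd2=0.95)


@pytest.fixture(scope="session")
def moderate_t(moderate_summary):
    return pooled_t(moderate_summary)


@pytest.fixture(scope="session")
def wide_prior():
    return CauchyPrior(0.0, 1.0)


@pytest.fixture(scope="session")
def default_region():
    return EquivalenceRegion(-0.1, 0.1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
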