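import numpy as np
import pytest

from receptorpharm import FunctionalParams, SystemParams


@pytest.fixture
def agonist_concs():
    """13-point half-decade agonist series, 1 pM - 1 uM (molar)."""
    return np.logspace(-12, -6, 13)


@pytest.fixture
def competitor_concs():
    """Competition series with zero-competitor (B0) wells, molar."""
    return np.concatenate([[0.0], np.logspace(-11, -5, 13)])


@pytest.fixture
def kinetic_system():
    """Antagonist-radioligand-like membrane system, noise-free."""
    return SystemParams(bmax_cpm=2000.0, kon=0.308, koff=0.010, ns_fraction=0.02, noise_cv=0.0)


@pytest.fixture
def functional_noise_free():
    return FunctionalParams(ec50_nM=0.16, emax_frac=1.0, kb_nM=50.0, noise_cv=0.0)
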