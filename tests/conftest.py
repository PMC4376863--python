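import numpy as np
import pytest

from trifilament.crossbridge import default_crossbridge_params, default_overlap
from trifilament.polymer import ExtensibleWLCParams, WLCParams
from trifilament.titin import TitinStrandState, default_isoform
from trifilament.unfolding import EnsembleConfig, UnfoldingParams


@pytest.fixture(scope="session")
def isoform():
    return default_isoform()


@pytest.fixture
def strand_state():
    return TitinStrandState()


@pytest.fixture(scope="session")
def wlc_params():
    # the worked example set: pl 1 nm, cl 100 nm, T 300 K
    return WLCParams(1.0, 100.0, 300.0)


@pytest.fixture(scope="session")
def ewlc_params():
    return ExtensibleWLCParams(1.0, 100.0, 300.0, elastic_modulus=1000.0)


@pytest.fixture(scope="session")
def cb_params():
    return default_crossbridge_params()


@pytest.fixture(scope="session")
def overlap_fn():
    return default_overlap()


@pytest.fixture
def unfolding_params():
    return UnfoldingParams()


@pytest.fixture
def small_ensemble_config():
    return EnsembleConfig(n_strands=50, rng_seed=123, time_step=1e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
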