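import numpy as np
import pytest

from ampbias.insilico_pcr import load_primer_panel
from ampbias.synthetic_data import SimulationConfig, generate_community


@pytest.fixture(scope="session")
def panel():
    return load_primer_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {p.marker_name: p for p in panel}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_truth():
    """A 5+4-species community: fast enough for per-test simulation."""
    cfg = SimulationConfig(n_fish=5, n_cetacean=4, depth=20_000, seed=11)
    _, truth = generate_community(cfg)
    return truth


@pytest.fixture()
def full_truth():
    """The default 12+14-species community."""
    cfg = SimulationConfig(seed=11)
    _, truth = generate_community(cfg)
    return truth
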