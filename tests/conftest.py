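import numpy as np
import pytest

from domcert.observations import build_winloss
from domcert.synthetic import (
    SimulationConfig,
    make_hierarchy,
    make_paper_regime_study,
    make_study,
    simulate_events,
)


@pytest.fixture(scope="session")
def paper_regime_study():
    """The default full-size fixture (3 groups of ~120), built once."""
    return make_paper_regime_study(seed=0)


@pytest.fixture(scope="session")
def small_study():
    """A fast two-group study for pipeline and round-trip tests."""
    cfg = SimulationConfig(group_sizes=(16, 18), seed=7)
    return make_study(cfg)


@pytest.fixture(scope="session")
def medium_winloss():
    """A 30-animal win/loss matrix in the steep sparse regime."""
    rng = np.random.default_rng(11)
    hier = make_hierarchy(30)
    events = simulate_events(hier, 1500, rng)
    return hier, build_winloss(events, hier.ids)
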