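import numpy as np
import pytest
from hypothesis import settings

import bycatchclim as bc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return bc.load_table1()


@pytest.fixture(scope="session")
def preset_run():
    """One simulated study under the study-scale preset, seed 1."""
    config = bc.table1_like_scenario(seed=1)
    index = bc.simulate_monthly_index(config)
    sets = bc.simulate_fishery(config, index)
    return config, index, sets


def make_events(outcomes, covariate, label="test"):
    outcomes = np.asarray(outcomes)
    return bc.BinaryEventSeries(
        years=tuple(range(2000, 2000 + len(outcomes))),
        outcomes=outcomes,
        covariate=np.asarray(covariate, dtype=float),
        label=label,
    )
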