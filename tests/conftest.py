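import numpy as np
import pytest

from placemem.events import default_stimulus_roster
from placemem.simulate import RECALL_CONDITION_COUNTS, make_ground_truth


@pytest.fixture(scope="session")
def roster():
    return default_stimulus_roster(RECALL_CONDITION_COUNTS)


@pytest.fixture(scope="session")
def stimuli(roster):
    return [s for v in roster.values() for s in v]


@pytest.fixture(scope="session")
def condition_of(stimuli):
    return {s: s.rsplit("_", 1)[0] for s in stimuli}


@pytest.fixture
def small_truth_factory(stimuli):
    """Ground truth with two small ROIs; keyword overrides forwarded."""

    def factory(**kwargs):
        defaults = dict(
            roi_sizes={"memory": 24, "perception": 24},
            amplitudes={
                "memory": {"image": 0.5, "panorama": 1.0, "street": 1.5},
                "perception": {"image": 1.0, "panorama": 1.0, "street": 1.0},
            },
            stimuli=stimuli,
            rho_id=0.0,
            sigma_white=0.0,
            ar1_phi=0.0,
            drift_amplitude=0.0,
            seed=0,
        )
        defaults.update(kwargs)
        return make_ground_truth(**defaults)

    return factory
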