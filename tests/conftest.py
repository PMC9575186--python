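import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sigrobust.scenarios import (
    confounded_scenario_config,
    run_robustness_scenario,
    signal_scenario_config,
)

N_REPS = 100  # replicate count for the null batteries


@pytest.fixture(scope="session")
def signal_result():
    """Null batteries on the signature-driven world (subtype signal real)."""
    return run_robustness_scenario(signal_scenario_config(seed=1), n_reps=N_REPS, seed=1)


@pytest.fixture(scope="session")
def confounded_result():
    """Null batteries on the purity-confounded world (labels = contamination bins)."""
    return run_robustness_scenario(confounded_scenario_config(seed=1), n_reps=N_REPS, seed=1)
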