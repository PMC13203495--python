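"""Shared fixtures: the scaled nested/unprotected reference runs.

Both scenario runs are session-scoped because they dominate the suite's
runtime; every test that inspects the coupled simulation reads from these.
"""

import pytest

from nestedfsi.pipeline import SimulationConfig, run_simulation


@pytest.fixture(scope="session")
def nested_run():
    """The default scaled protected scenario: 2-D nested model, 6 s of
    calibrated seizure roll forcing (3 convulsion cycles at 0.5 Hz)."""
    return run_simulation(SimulationConfig(total_time=6.0, seed=0))


@pytest.fixture(scope="session")
def unprotected_run():
    """Same scale and forcing with the fluid layers removed and the
    protective gaps collapsed to direct penalty contact."""
    return run_simulation(
        SimulationConfig(total_time=6.0, seed=0, scenario="no_fluids"))
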