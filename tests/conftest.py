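import pytest
from hypothesis import settings

import odrs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> odrs.DeviceConfig:
    return odrs.default_config()


@pytest.fixture(scope="session")
def default_traj(default_cfg) -> odrs.Trajectory:
    """First injection cycle with the calibrated default preset (shared:
    the cycle is deterministic)."""
    return odrs.simulate_cycle(default_cfg)


@pytest.fixture(scope="session")
def three_dose_trajs(default_cfg, default_traj):
    """Three chained cycles from a single device charge."""
    trajs = [default_traj]
    state = default_traj.final_state
    for _ in range(2):
        traj = odrs.simulate_cycle(default_cfg, state)
        trajs.append(traj)
        state = traj.final_state
    return trajs
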