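import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipgain.config import NetworkConfig, TrialProtocol
from lipgain.experiment import TrialRecord, run_experiment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture(scope="session")
def small_records(default_config) -> list[TrialRecord]:
    """A small but fully realistic run shared by decoder/GFI unit tests."""
    proto = TrialProtocol(n_trials=8, seed=777)
    return run_experiment(default_config, proto)


def make_toy_record(
    trial_id: int,
    n_steps: int = 10,
    n: int = 2,
    dt: float = 5.0,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Tiny synthetic TrialRecord for index-arithmetic oracles."""
    rng = rng or np.random.default_rng(trial_id)
    time = np.arange(n_steps) * dt - 2 * dt
    return TrialRecord(
        trial_id=trial_id,
        onset=0.0,
        time=time,
        lip_cd=rng.random((n_steps, n, n)).astype(np.float32),
        lip_pc=rng.random((n_steps, n, n)).astype(np.float32),
        eye=rng.random(n_steps),
        delays=np.full((n, n), 150.0),
    )
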