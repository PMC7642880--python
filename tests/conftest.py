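import numpy as np
import pandas as pd
import pytest

from addhrv import MethodConfig, SampleGrid, SimParams, simulate_cohort

WINDOWS_PER_DAY = 2880


def make_grid(
    rmssd,
    acc,
    window_s: float = 30.0,
    asleep=None,
    participant_id: str = "P01",
) -> SampleGrid:
    """Small grid from explicit per-window values (NaN = missing)."""
    rmssd = np.asarray(rmssd, dtype=float)
    acc = np.asarray(acc, dtype=float)
    n = len(rmssd)
    index = np.arange(n)
    frame = pd.DataFrame(
        {
            "index": index,
            "day": (index * window_s // 86400).astype(int) + 1,
            "hour": ((index * window_s // 3600) % 24).astype(int),
            "rmssd_ms": rmssd,
            "acc_g": acc,
            "asleep": np.zeros(n, dtype=bool) if asleep is None else np.asarray(asleep, bool),
        }
    )
    return SampleGrid(participant_id, window_s, frame)


@pytest.fixture
def default_cfg() -> MethodConfig:
    return MethodConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Two participants, two days, default generator settings."""
    return simulate_cohort(SimParams(n_participants=2, days=2, seed=11))


@pytest.fixture(scope="session")
def clean_day():
    """One participant, one day, movement-only world (no circadian term,
    no sleep baseline shift, no injected episodes, no noise)."""
    params = SimParams(
        n_participants=1,
        days=1,
        seed=5,
        noise_sd=0.0,
        circadian_amp=0.0,
        sleep_b0_bonus=0.0,
        episode_rate=0.0,
        spurious_report_rate=0.0,
        calibration_stress_mult=1.0,
    )
    return simulate_cohort(params)[0]
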