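import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from drowsyhrv.iodata import ECG, IBISeries
from drowsyhrv.synthetic_data import CohortConfig, generate_cohort


def make_series(rr_ms, subject="sX", device=ECG) -> IBISeries:
    """Series from an RR list (ms), beat times as cumulative sums."""
    rr = np.asarray(rr_ms, dtype=float)
    t = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return IBISeries(subject_id=subject, device=device, beat_times=t, intervals=rr)


def random_rr_window(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """A plausible RR window: baseline + LF/HF tones + noise (ms)."""
    n = n or int(rng.integers(150, 400))
    t = np.cumsum(rng.uniform(0.7, 1.1, n))
    return (
        850.0
        + rng.uniform(5, 40) * np.sin(2 * np.pi * 0.10 * t)
        + rng.uniform(5, 40) * np.sin(2 * np.pi * 0.25 * t)
        + rng.normal(0, rng.uniform(5, 25), n)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject default-condition cohort, shared across tests."""
    return generate_cohort(CohortConfig(n_subjects=3), seed=7)
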