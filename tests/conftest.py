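import numpy as np
import pandas as pd
import pytest

from wibsplus.calibration import ThresholdSet
from wibsplus.io import FLUOR_CHANNELS
from wibsplus.synthetic import default_scenario

#: Seed of the documented default scenario used by the recovery tests.
SCENARIO_SEED = 20170421


def make_thresholds(mean: float = 100.0, sd: float = 10.0, k: int = 3) -> ThresholdSet:
    """Uniform per-channel thresholds for hand-built fixtures."""
    return ThresholdSet(
        mean={ch: mean for ch in FLUOR_CHANNELS},
        sd={ch: sd for ch in FLUOR_CHANNELS},
        k=k,
    )


def make_particles(rows, start="2017-05-01 00:00:00", step="1min") -> pd.DataFrame:
    """Particle frame from a list of dicts; missing fields get defaults.

    Timestamps default to an evenly spaced sequence so hand fixtures stay
    time-ordered.
    """
    base = pd.Timestamp(start)
    step = pd.Timedelta(step)
    records = []
    for i, row in enumerate(rows):
        rec = {
            "timestamp": base + i * step,
            "size": 5.0,
            "af": 10.0,
            **{ch: 0.0 for ch in FLUOR_CHANNELS},
        }
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def default_bundle():
    """The full 50-day default scenario at the documented seed."""
    return default_scenario(SCENARIO_SEED, days=50)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
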