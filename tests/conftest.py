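import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from walisar.preference_metrics import FlyTrack

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_track(x_positions, lit_half, dt=1.0, chamber=50.0, **meta):
    """Hand-built track: one frame per entry, constant frame spacing."""
    n = len(x_positions)
    defaults = dict(fly_id="f0", role="test", orn_label="OrX",
                    intensity="14", airflow="off", step_index=1, epoch="second")
    defaults.update(meta)
    lit = lit_half if not isinstance(lit_half, str) else [lit_half] * n
    frames = pd.DataFrame({
        "time_s": np.arange(n) * dt,
        "x_mm": np.asarray(x_positions, dtype=float),
        "lit_half": list(lit),
    })
    return FlyTrack(frames=frames, chamber_length_mm=chamber, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_track():
    """60-s lit window: 30 s dark, then 20 s in light, then 10 s in dark.

    The fly first enters the lit (left) half at t = 30 s, giving
    TSALE = (20-10)/30 = 1/3, weight = 30/60 = 1/2, wTSALE = 1/6.
    """
    x = [40.0] * 30 + [10.0] * 20 + [40.0] * 10
    return make_track(x, "left")
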