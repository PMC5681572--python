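import numpy as np
import pandas as pd
import pytest

from lamidelay.synthgen import (
    ScenarioConfig,
    cascade_recovery_config,
    generate_events,
)
from lamidelay.types import EVENT_COLUMNS


def make_events(records) -> pd.DataFrame:
    """Event table from (hemisphere, layer, time_ms[, epoch]) tuples, one animal."""
    rows = []
    for rec in records:
        hemi, layer, t = rec[:3]
        epoch = rec[3] if len(rec) > 3 else 0
        rows.append((0, epoch, "evoked", hemi, layer, float(t)))
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def random_events(rng: np.random.Generator, n: int, n_epochs: int = 5,
                  span_ms: float = 100.0) -> pd.DataFrame:
    """Random events over all 12 channels, several epochs."""
    hemis = np.array(["contra", "ipsi"])[rng.integers(0, 2, n)]
    return pd.DataFrame(
        {
            "animal_id": 0,
            "epoch": rng.integers(0, n_epochs, n),
            "regime": "evoked",
            "hemisphere": hemis,
            "layer": rng.integers(1, 7, n),
            "time_ms": rng.uniform(0, span_ms, n),
        }
    )


@pytest.fixture(scope="session")
def recovery_data():
    """Clean layer-step cascade scenario (0.3 ms/step, 0.1 ms jitter)."""
    cfg = cascade_recovery_config(seed=0)
    events, truth = generate_events(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def noiseless_cascade():
    """Deterministic cascade with no background, no jitter (0.3 ms/step)."""
    cfg = ScenarioConfig(
        n_animals=1,
        n_epochs=20,
        regime="evoked",
        rates_hz={h: (0.0,) * 6 for h in ("contra", "ipsi")},
        cascade_lag_ms=0.3,
        jitter_sd_ms=0.0,
        participation={layer: 1.0 for layer in range(1, 7)},
        relay_superficial_increment_ms=0.3,
        active_gain=0.0,
        seed=0,
    )
    events, truth = generate_events(cfg)
    return cfg, events, truth
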