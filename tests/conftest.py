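import numpy as np
import pandas as pd
import pytest

from recruitlag import synthetic_data as sd
from recruitlag.campaign_io import CHANNELS


@pytest.fixture(scope="session")
def fixture_data():
    """Deterministic participant table + cost ledger matching the printed margins."""
    return sd.build_fixture()


@pytest.fixture(scope="session")
def montreal_sim():
    """One Montreal-like simulated campaign: (config, schedule, daily recruits)."""
    cfg = sd.SimConfig(sigma=2.0)
    sch = sd.generate_schedule(cfg, seed=11)
    daily = sd.simulate_recruits(sch, cfg, seed=12)
    return cfg, sch, daily


def make_schedule(values: dict[str, np.ndarray] | None = None, T: int = 10) -> pd.DataFrame:
    """Small schedule helper: all-zero channels except the ones given."""
    df = pd.DataFrame({"day_index": np.arange(T, dtype=int)})
    for ch in CHANNELS:
        df[ch] = 0.0
    for ch, vals in (values or {}).items():
        df[ch] = np.asarray(vals, dtype=float)
    return df
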