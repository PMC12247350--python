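import numpy as np
import pandas as pd
import pytest

from trackfidelity.config import PipelineConfig
from trackfidelity.pipeline import run_all
from trackfidelity.synthetic import SimConfig


def make_track(lons, lats, times_h, bird="b1", lc="3", t0="2020-01-01"):
    """Build a fix table from coordinate/hour-offset arrays."""
    base = pd.Timestamp(t0, tz="UTC")
    return pd.DataFrame({
        "bird_id": bird,
        "timestamp": [base + pd.Timedelta(hours=float(h)) for h in times_h],
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "lc": lc,
        "error_radius_m": np.nan,
    })


@pytest.fixture(scope="session")
def small_population():
    """A compact simulated population shared across tests."""
    from trackfidelity.synthetic import generate_population
    cfg = SimConfig(n_birds=5, n_years=3, seed=42)
    fixes, truth = generate_population(cfg)
    return cfg, fixes, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline on a moderate population; reused by the end-to-end
    acceptance checks (expensive: built once per session)."""
    cfg = PipelineConfig(seed=7, n_boot=200,
                         sim=SimConfig(n_birds=12, n_years=3, seed=7))
    return run_all(cfg)
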