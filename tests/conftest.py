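import numpy as np
import pandas as pd
import pytest

from valvometry.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """6-day, 2-clam simulated deployment shared across read-only tests."""
    cfg = SimulationConfig(seed=11, n_days=6, n_clams=2)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_valve(values, start="2021-05-03", period_s=60.0, clam_id=1):
    from valvometry.series import ValveSeries

    idx = pd.date_range(start, periods=len(values),
                        freq=pd.Timedelta(seconds=period_s))
    return ValveSeries(clam_id=clam_id,
                       data=pd.Series(np.asarray(values, dtype=float), index=idx),
                       nominal_period_s=period_s)
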