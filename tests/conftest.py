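import numpy as np
import pandas as pd
import pytest

import cgrsens as cs


@pytest.fixture(scope="session")
def truth():
    return cs.SyntheticTruth(seed=42)


@pytest.fixture(scope="session")
def climate(truth):
    return cs.gen_climate(truth)


@pytest.fixture(scope="session")
def station(truth, climate):
    record, annual_truth = cs.gen_co2(truth, climate)
    return record, annual_truth


@pytest.fixture(scope="session")
def annual_table(truth, climate, station):
    """Joined annual table: detrended CGR + climate anomalies."""
    record, _ = station
    ann = cs.annual_cgr(cs.monthly_cgr(record))
    table = cs.align(ann, cs.annual_anomalies(climate.monthly))
    table["cgr"] = cs.detrend_linear(table["cgr"])
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_anomaly_frame(rng, n=20, seed=None):
    """Small synthetic anomaly design for direct regression tests."""
    r = rng if seed is None else np.random.default_rng(seed)
    df = pd.DataFrame({
        "dT": r.normal(0, 0.2, n),
        "dP": r.normal(0, 40.0, n),
        "dR": r.normal(0, 1.5, n),
    }, index=pd.RangeIndex(1960, 1960 + n, name="year"))
    return df
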