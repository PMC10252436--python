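import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from oilrisk import SyntheticConfig, generate
from oilrisk.indices import compute_triples
from oilrisk.preprocessing import substitute_nondetects, summarize

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_data():
    """The default synthetic campaign at seed 42: (sampling, consumption,
    truth) tables."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def default_triples(default_data):
    sampling, consumption, _ = default_data
    summaries = summarize(substitute_nondetects(sampling))
    return compute_triples(summaries, consumption)


@pytest.fixture(scope="session")
def truth_levels(default_data, default_triples):
    """Planted level per triple row, aligned with default_triples."""
    _, _, truth = default_data
    keyed = truth.set_index(["city", "week"])["level"]
    idx = list(zip(default_triples["city"], default_triples["week"]))
    return keyed.loc[idx].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture()
def toy_records():
    """Four records, one censored (25% non-detects)."""
    return pd.DataFrame(
        {
            "province": ["A"] * 4,
            "city": ["A-1"] * 4,
            "week": [1, 1, 2, 2],
            "concentration": [0.5, 1.0, np.nan, 2.0],
            "detected": [True, True, False, True],
        }
    )
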