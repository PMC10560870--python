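import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_counts():
    """5 genera x 4 samples, totals 1e6 per sample, with one genus planted
    below the cellwise RRA threshold and one below the mean-RRA threshold."""
    big = 1_000_000
    # D: cell RRA 5e-6 < 0.001% everywhere -> zeroed, then dropped.
    # E: cell RRA 3e-5 >= 0.001% but mean RRA ~3e-5 < 0.01% -> dropped.
    data = {f"S{k}": [400_000, 350_000, 249_965, 5, 30] for k in range(1, 5)}
    counts = pd.DataFrame(data, index=["A", "B", "C", "D", "E"])
    assert (counts.sum(axis=0) == big).all()
    return counts


@pytest.fixture(scope="session")
def small_samples():
    rng = np.random.default_rng(0)
    n = 12
    idx = [f"H{h:02d}-T{t}" for h in range(1, 5) for t in (1, 2, 3)]
    return pd.DataFrame(
        {
            "beekeeper": ["B01", "B01", "B02", "B02"] * 3,
            "hive": [s.split("-")[0] for s in idx],
            "site": ["S1", "S2", "S1", "S2"] * 3,
            "site_x": [0.0, 10.0, 0.0, 10.0] * 3,
            "site_y": [0.0, 0.0, 0.0, 0.0] * 3,
            "timepoint": ["June", "July", "August"] * 4,
            "total_reads": rng.integers(5e5, 2e6, size=n),
        },
        index=pd.Index(idx, name="sample"),
    )
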