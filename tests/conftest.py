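import numpy as np
import pandas as pd
import pytest

from omnisub.containers import OmicsMatrix, Partition, SurvivalTable
from omnisub.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def small_survival() -> SurvivalTable:
    rng = np.random.default_rng(42)
    n = 60
    df = pd.DataFrame(
        {"event": rng.integers(0, 2, n),
         "time_days": rng.permutation(np.arange(1.0, n + 1.0))},
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="patient_id"))
    df.iloc[0, 0] = 1  # guarantee events
    df.iloc[1, 0] = 1
    return SurvivalTable(df)


@pytest.fixture
def small_cohort():
    cfg = SimulationConfig(
        n_patients=120, k_true=3,
        platform_dims={"mrna": 120, "protein": 40},
        hazard_per_subtype=(0.004, 0.0015, 0.0008),
        frac_informative=0.2, effect_size=2.0, censor_rate=0.3, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture
def two_blob_matrix() -> OmicsMatrix:
    """Six samples in two tight, well-separated 3-sample groups."""
    rng = np.random.default_rng(5)
    base = np.zeros((8, 6))
    base[:, 3:] += 10.0
    base += rng.normal(0, 0.1, base.shape)
    df = pd.DataFrame(base, index=[f"g{i}" for i in range(8)],
                      columns=[f"s{i}" for i in range(6)])
    return OmicsMatrix("protein", df)


def make_partition(labels, method="PAM") -> Partition:
    s = pd.Series(labels)
    s.index = [f"S{i}" for i in range(len(s))]
    return Partition(method, int(s.max()), s)
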