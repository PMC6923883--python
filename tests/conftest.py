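import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from skewcohort import skewcore, synthdata

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted links, shared across read-only tests."""
    cfg = synthdata.CohortConfig(
        n_genes=120,
        n_samples=200,
        linked_fraction=0.25,
        methyl_shift={"Promoter": -1.0},
        target_corr=-0.8,
        seed=7,
    )
    return synthdata.generate_cohort(cfg)


@pytest.fixture
def expr_frame(rng):
    """Plain 50-gene x 60-sample expression DataFrame, right-skewed genes."""
    base = rng.normal(8.0, 1.0, size=(50, 60))
    base[:, :6] += 3.0  # minority subgroup shifted up
    return pd.DataFrame(
        base,
        index=[f"G{i:03d}" for i in range(50)],
        columns=[f"S{j:03d}" for j in range(60)],
    )


def brute_force_skewness(x):
    """Independent oracle for the skewness statistic: literal evaluation of
    the cube-root-third-moment-over-sd definition with explicit loops."""
    x = list(float(v) for v in x)
    n = len(x)
    mu = sum(x) / n
    m3 = sum((v - mu) ** 3 for v in x) / (n - 1)
    var = sum((v - mu) ** 2 for v in x) / (n - 1)
    sd = var**0.5
    root = abs(m3) ** (1 / 3) * (1 if m3 >= 0 else -1)
    return root / sd
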