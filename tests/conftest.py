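import numpy as np
import pandas as pd
import pytest

from dmdir import ScenarioConfig, simulate_cohort


def small_config(**kw):
    """A fast k=3 configuration used across the unit tests."""
    base = dict(direction="xgy", scenario="uni1c", n=120, m=40, m_true=4, k=3,
                dirichlet_alpha=(3.0, 2.0, 1.0), effect_size=2.0, seed=7)
    base.update(kw)
    return ScenarioConfig(**base)


@pytest.fixture(scope="session")
def small_xgy():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_ygx():
    return simulate_cohort(small_config(direction="ygx"))


def table_from_pvalues(p, cpg_prefix="cpg", k=1):
    """Minimal association table with given p-values (one cell type)."""
    p = np.asarray(p, dtype=float)
    return pd.DataFrame({
        "cpg": [f"{cpg_prefix}{i}" for i in range(p.size)],
        "cell_type": ["ct1"] * p.size,
        "estimate": np.zeros(p.size),
        "std_error": np.ones(p.size),
        "statistic": np.zeros(p.size),
        "p_value": p,
    })
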