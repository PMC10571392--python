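import numpy as np
import pandas as pd
import pytest

from metasig.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """Two small cohorts with planted effects, shared across read-only tests."""
    cfg = SimulationConfig(
        n_species=80,
        n_per_arm={(c, g): 40 for c in ("SH", "BJ") for g in ("HC", "ESRD")},
        frac_differential=0.2,
        effect_log2fc=2.0,
        seed=11,
    )
    return cfg, simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_table():
    return pd.DataFrame(
        [[0.5, 0.5, 0.0], [0.25, 0.75, 0.0], [0.0, 0.0, 1.0]],
        index=["a", "b", "c"],
        columns=["s1", "s2", "s3"],
    )
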