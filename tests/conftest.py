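import numpy as np
import pandas as pd
import pytest

from cfrna import normalize, simulate
from cfrna.io import WINDOW_EARLY


@pytest.fixture(scope="session")
def small_cohort():
    """Small full-structure cohort shared by downstream-stage tests."""
    design = simulate.SimulationDesign(
        cohorts={"discovery": (20, 10)},
        n_genes=600,
        seed=42,
    )
    cm, meta, truth = simulate.simulate_cohort(design)
    cm = normalize.logcpm(cm, normalize.tmm_factors(cm))
    return cm, meta, truth


@pytest.fixture(scope="session")
def early_only_cohort():
    """Single-window cohort (40/arm) for fold-change estimator checks."""
    design = simulate.SimulationDesign(
        cohorts={"discovery": (40, 40)},
        windows=(WINDOW_EARLY,),
        n_genes=1500,
        seed=3,
    )
    cm, meta, truth = simulate.simulate_cohort(design)
    cm = normalize.logcpm(cm, normalize.tmm_factors(cm))
    return cm, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_counts():
    return pd.DataFrame(
        [[10, 20], [0, 5], [3, 3]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
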