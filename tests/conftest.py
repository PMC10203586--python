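import warnings

import numpy as np
import pytest

from phenosel.evaluation import StudyData
from phenosel.simdata import SimConfig, TruthConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_sim():
    """Unit-test scale simulated study (4 crosses x 10 lines, 2 envs)."""
    return simulate_study(SimConfig.tiny(), seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A small 4-environment study prepared for evaluation: 6 crosses x 20
    lines, the full unbalanced replication pattern, genetic correlation 0.3."""
    cfg = SimConfig(
        n_parents=12,
        n_biparental=5,
        n_threeway=1,
        lines_per_cross=20,
        n_markers=120,
        n_chrom=7,
        truth=TruthConfig(n_qtl=40, env_corr=0.3),
    )
    sim = simulate_study(cfg, seed=23)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = StudyData.from_simulation(sim)
    return sim, data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
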