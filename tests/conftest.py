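import warnings

import numpy as np
import pytest

import vigiplay as v
from vigiplay.design import build_design
from vigiplay.model import ModelSpec, fit_lmm

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def ethogram():
    return v.load_ethogram()


@pytest.fixture(scope="session")
def weight_params():
    return v.WeightParams()


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated study (3 sessions/individual, ~198 trials)."""
    cfg = v.SimConfig(seed=42, sessions_per_individual=3)
    trials, features, truth = v.simulate_trials(cfg)
    return cfg, trials, features, truth


@pytest.fixture(scope="session")
def toy_fit(small_sim):
    """One fitted raw model shared across contrast/identity tests."""
    _, trials, features, _ = small_sim
    design = build_design(trials, features)
    fit = fit_lmm(design, ModelSpec(chains=2, iterations=1200, warmup=600, seed=99))
    return design, fit
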