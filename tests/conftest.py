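import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import giquant as gq

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_effects() -> gq.TrueEffects:
    """2 queries x 2 genes with one injected aggravating interaction."""
    return gq.TrueEffects(
        wt_fitness=7.0,
        query_effects={"q1": -0.2, "q2": -0.1},
        gene_effects={"g1": -0.15, "g2": -0.05},
        interactions={("q1", "g1"): -0.4},
    )


@pytest.fixture
def null_effects() -> gq.TrueEffects:
    return gq.TrueEffects(
        wt_fitness=7.0,
        query_effects={"q1": 0.0, "q2": 0.0},
        gene_effects={"g1": 0.0, "g2": 0.0},
    )


def make_config(effects: gq.TrueEffects, seed: int = 1, **kwargs) -> gq.SimulationConfig:
    return gq.SimulationConfig(seed=seed, true_effects=effects, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
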