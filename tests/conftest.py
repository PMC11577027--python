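import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from soilwebflux.diet import PreferenceMatrix
from soilwebflux.synth import default_taxon_pool
from soilwebflux.traits import RESOURCE_TYPES


@pytest.fixture(scope="session")
def pool():
    """The generator's 30-taxon trait table."""
    return default_taxon_pool()


def random_web(rng: np.random.Generator, max_nodes: int = 30):
    """A random valid (column-stochastic, feasible) web and its losses.

    Animal diet fractions are capped at 0.6, below the level at which
    predation loops could outgrow the diet-weighted assimilation
    efficiency, so every generated web has a nonnegative steady state
    and the fixed-point iteration converges. Cycles are allowed.
    """
    n_basal = int(rng.integers(1, 4))
    basal_types = list(rng.choice(RESOURCE_TYPES, size=n_basal, replace=False))
    n_anim = int(rng.integers(2, max_nodes - n_basal + 1))
    n = n_anim + n_basal
    W = np.zeros((n, n))
    for j in range(n_anim):
        prey_mask = rng.random(n_anim) < 0.5
        prey_mask[j] = False
        w = rng.random(n_anim) * prey_mask
        a_frac = float(rng.uniform(0.0, 0.6)) if w.sum() > 0 else 0.0
        basal_w = rng.random(n_basal)
        basal_w /= basal_w.sum()
        if a_frac > 0:
            W[:n_anim, j] = a_frac * w / w.sum()
        W[n_anim:, j] = (1.0 - a_frac) * basal_w
    X = rng.uniform(0.1, 5.0, size=n_anim)
    ids = [f"n{i}" for i in range(n)]
    types = ["animal"] * n_anim + basal_types
    return PreferenceMatrix(ids, types, W), X


@pytest.fixture(scope="session")
def random_web_suite():
    """1,000 random valid webs of up to 30 nodes, shared across tests."""
    rng = np.random.default_rng(20240)
    return [random_web(rng) for _ in range(1000)]
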