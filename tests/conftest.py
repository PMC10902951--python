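import numpy as np
import pytest

from pathsurv.data_io import PathwayMask, SurvivalOutcome
from pathsurv.network import NetworkConfig, init_model
from pathsurv.synthetic import SyntheticSpec, simulate_cohort, simulate_pathways
from pathsurv.data_io import build_pathway_mask


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_mask(rng, q=4, p=20, density=0.4):
    """Random binary pathway mask with every gene and pathway covered."""
    m = (rng.uniform(size=(q, p)) < density).astype(float)
    m[0, m.sum(axis=0) == 0] = 1.0
    m[m.sum(axis=1) == 0, 0] = 1.0
    return PathwayMask(m, [f"P{i}" for i in range(q)], [f"g{j}" for j in range(p)])


def randomized_state(rng, mask, scale=0.5, **config_kw):
    """Model with O(1) random weights so ReLU preactivations sit away from
    their kinks (finite-difference checks need that margin)."""
    defaults = dict(n_hidden1=8, n_hidden2=6, n_embedding=3, seed=1)
    defaults.update(config_kw)
    state = init_model(NetworkConfig(**defaults), mask)
    for k, v in state.params.items():
        state.params[k] = rng.normal(0.0, scale, size=v.shape)
    state.params["Ws"] *= state.mask_t
    return state


def random_survival(rng, n, censor_frac=0.4):
    time = rng.uniform(0.5, 10.0, size=n)
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return SurvivalOutcome([f"s{i}" for i in range(n)], time, event)


@pytest.fixture
def toy_mask(rng):
    return random_mask(rng)


@pytest.fixture
def toy_state(rng, toy_mask):
    return randomized_state(rng, toy_mask)


@pytest.fixture(scope="session")
def tiny_study():
    """Small cohort + mask shared by training/CLI-level tests."""
    spec = SyntheticSpec(
        n_samples=80, n_genes=40, n_pathways=5, pathway_size=8,
        planted_genes=6, effect_size=1.0, target_censoring=0.3, seed=11,
    )
    cohort, truth = simulate_cohort(spec)
    pathways = simulate_pathways(spec)
    mask = build_pathway_mask(pathways, cohort.expression.gene_ids)
    return spec, cohort, truth, pathways, mask
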