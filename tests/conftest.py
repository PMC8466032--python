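import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bnkl import (
    BayesianNetwork,
    GeneratorSpec,
    Potential,
    Variable,
    perturb_network,
    random_network,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_variables(cards, prefix="X"):
    return [
        Variable(f"{prefix}{i + 1}", tuple(f"s{j}" for j in range(c)), i)
        for i, c in enumerate(cards)
    ]


@pytest.fixture
def chain():
    """X1 -> X2 -> X3, binary, fixed CPTs (the running three-variable chain)."""
    return BayesianNetwork.from_cpt_arrays(
        {"X1": ["0", "1"], "X2": ["0", "1"], "X3": ["0", "1"]},
        {"X2": ["X1"], "X3": ["X2"]},
        {
            "X1": [0.3, 0.7],
            "X2": np.array([[0.9, 0.4], [0.1, 0.6]]),  # P(X2|X1)
            "X3": np.array([[0.2, 0.5], [0.8, 0.5]]),  # P(X3|X2)
        },
        name="chain",
    )


def make_fig_pair(seed=0):
    """The three-variable worked-example pair.

    NA has families {X1}, {X1,X2}, {X1,X3} (X1 -> X2, X1 -> X3);
    NB replaces X3's parent by X2 so its third family is {X2,X3}.
    CPT values are drawn from Dirichlet(1) -- the plan trace depends only
    on the structures.
    """
    rng = np.random.default_rng(seed)
    states = {"X1": ["0", "1"], "X2": ["0", "1"], "X3": ["0", "1"]}

    def cpt(n_cols):
        return rng.dirichlet([1.0, 1.0], size=n_cols).T

    na = BayesianNetwork.from_cpt_arrays(
        states,
        {"X2": ["X1"], "X3": ["X1"]},
        {"X1": rng.dirichlet([1.0, 1.0]), "X2": cpt(2), "X3": cpt(2)},
        name="NA",
    )
    nb = BayesianNetwork.from_cpt_arrays(
        states,
        {"X2": ["X1"], "X3": ["X2"]},
        {"X1": rng.dirichlet([1.0, 1.0]), "X2": cpt(2), "X3": cpt(2)},
        name="NB",
    )
    return na, nb.aligned_with(na)


@pytest.fixture
def fig_pair():
    return make_fig_pair()


def make_random_pair(seed, n_vars=8, max_parents=3, edge_moves=3, cards=(2, 2)):
    """A reference network and a structure-perturbed copy (study conditions:
    8 binary variables, at most 3 parents, Dirichlet(1) CPTs, 3 edge moves)."""
    spec = GeneratorSpec(
        n_vars=n_vars,
        max_parents=max_parents,
        cardinalities=cards,
        dirichlet_alpha=1.0,
        seed=seed,
    )
    na = random_network(spec)
    nb = perturb_network(na, edge_moves, seed + 1_000_003, max_parents=max_parents)
    return na, nb


@pytest.fixture
def random_pair():
    return make_random_pair(7)


def random_potential(rng, variables):
    shape = tuple(v.cardinality for v in variables)
    return Potential(variables, rng.random(shape))
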