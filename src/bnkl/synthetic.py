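"""Synthetic network pairs: random DAG + Dirichlet CPTs, and perturbations.

The generator emulates the original-vs-learned network setting used when
benchmarking structure learning: a reference network is drawn at random
(random topological order, bounded in-degree, CPT columns from a symmetric
Dirichlet), and a second network over the same variables is obtained by
random edge additions / removals / reversals with CPT re-sampling for the
changed families.  All draws come from a single ``numpy`` Generator seeded
from the spec, so every artifact is reproducible from its seed.

``forward_sample`` draws ancestral (topological-order) samples, as used to
create training data for learning procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BayesianNetwork
from .potentials import Potential, Variable

__all__ = ["GeneratorSpec", "random_network", "perturb_network", "forward_sample"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-network generator.

    cardinalities is an inclusive (min, max) range; dirichlet_alpha is the
    symmetric Dirichlet concentration for CPT columns (1.0 = uniform over
    the simplex).
    """

    n_vars: int
    max_parents: int = 3
    cardinalities: tuple[int, int] = (2, 2)
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vars < 1:
            raise ValueError("n_vars must be at least 1")
        if not 0 <= self.max_parents < self.n_vars:
            raise ValueError("max_parents must satisfy 0 <= max_parents < n_vars")
        lo, hi = self.cardinalities
        if not 2 <= lo <= hi:
            raise ValueError("cardinalities must satisfy 2 <= min <= max")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


def _dirichlet_cpt(
    rng: np.random.Generator, card: int, parent_cards: tuple[int, ...], alpha: float
) -> np.ndarray:
    """CPT array with axes (child, parents...), one Dirichlet draw per column."""
    n_cols = 1
    for c in parent_cards:
        n_cols *= c
    draws = rng.dirichlet(np.full(card, alpha), size=n_cols)  # (n_cols, card)
    return draws.T.reshape((card,) + parent_cards)


def random_network(spec: GeneratorSpec, *, name: str = "synthetic") -> BayesianNetwork:
    """Draw a random network: DAG over a random topological order + CPTs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vars
    lo, hi = spec.cardinalities
    cards = rng.integers(lo, hi + 1, size=n)
    variables = [
        Variable(f"X{i + 1}", tuple(f"s{j}" for j in range(cards[i])), i)
        for i in range(n)
    ]
    topo = list(rng.permutation(n))
    position = {vi: p for p, vi in enumerate(topo)}
    parents: dict[Variable, tuple[Variable, ...]] = {}
    for i, v in enumerate(variables):
        pos = position[i]
        preds = [topo[p] for p in range(pos)]
        k = int(rng.integers(0, min(spec.max_parents, pos) + 1))
        chosen = sorted(rng.choice(preds, size=k, replace=False)) if k else []
        parents[v] = tuple(variables[j] for j in chosen)
    cpts: dict[Variable, Potential] = {}
    for v in variables:
        ps = parents[v]
        arr = _dirichlet_cpt(
            rng, v.cardinality, tuple(p.cardinality for p in ps), spec.dirichlet_alpha
        )
        cpts[v] = Potential((v,) + ps, arr, check=False)
    return BayesianNetwork(variables, parents, cpts, name=name)


def _feasible_moves(
    g_parents: dict[int, set[int]], n: int, max_parents: int | None
) -> list[tuple[str, int, int]]:
    """All acyclicity- and in-degree-preserving single edge moves."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for child, ps in g_parents.items():
        for p in ps:
            g.add_edge(p, child)
    cap = n if max_parents is None else max_parents
    moves: list[tuple[str, int, int]] = []
    edges = list(g.edges())
    edge_set = set(edges)
    for u in range(n):
        for v in range(n):
            if u == v or (u, v) in edge_set or (v, u) in edge_set:
                continue
            if len(g_parents[v]) < cap and not nx.has_path(g, v, u):
                moves.append(("add", u, v))
    for u, v in edges:
        moves.append(("remove", u, v))
    for u, v in edges:
        if len(g_parents[u]) >= cap:
            continue
        g.remove_edge(u, v)
        if not nx.has_path(g, u, v):
            moves.append(("reverse", u, v))
        g.add_edge(u, v)
    return moves


def perturb_network(
    net: BayesianNetwork,
    n_edge_moves: int,
    seed: int,
    *,
    max_parents: int | None = None,
    dirichlet_alpha: float = 1.0,
) -> BayesianNetwork:
    """Structure-perturbed copy of ``net`` playing the learned-network role.

    Applies ``n_edge_moves`` random edge additions / removals / reversals,
    each chosen uniformly over the currently feasible moves (feasible =
    keeps the graph acyclic and respects ``max_parents``).  CPTs of families
    whose parent set changed are re-sampled from a symmetric Dirichlet; all
    other CPTs and every variable / state space are kept identical.  With
    ``n_edge_moves=0`` the result equals ``net``.
    """
    if n_edge_moves < 0:
        raise ValueError("n_edge_moves must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(net)
    g_parents: dict[int, set[int]] = {
        v.index: {p.index for p in net.parents[v]} for v in net.variables
    }
    for _ in range(n_edge_moves):
        moves = _feasible_moves(g_parents, n, max_parents)
        if not moves:
            break
        kind, u, v = moves[int(rng.integers(len(moves)))]
        if kind == "add":
            g_parents[v].add(u)
        elif kind == "remove":
            g_parents[v].discard(u)
        else:  # reverse u->v into v->u
            g_parents[v].discard(u)
            g_parents[u].add(v)
    parents = {
        v: tuple(net.variables[j] for j in sorted(g_parents[v.index]))
        for v in net.variables
    }
    cpts: dict[Variable, Potential] = {}
    for v in net.variables:
        if set(parents[v]) == set(net.parents[v]):
            cpts[v] = net.cpts[v]
        else:
            arr = _dirichlet_cpt(
                rng,
                v.cardinality,
                tuple(p.cardinality for p in parents[v]),
                dirichlet_alpha,
            )
            cpts[v] = Potential((v,) + parents[v], arr, check=False)
    return BayesianNetwork(
        net.variables, parents, cpts, name=f"{net.name}_perturbed"
    )


def forward_sample(net: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Ancestral sampling: ``n`` rows of state labels, one column per variable.

    Columns follow the network's declaration order; write with
    ``df.to_csv(path, index=False)`` for the CSV interchange form.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    codes: dict[str, np.ndarray] = {}
    for v in net.topological_order():
        cpt = net.cpts[v]
        child_ax = cpt.variables.index(v)
        arr = np.moveaxis(cpt.table, child_ax, 0)  # (card, parent axes...)
        pvars = [u for u in cpt.variables if u != v]
        if pvars:
            pidx = tuple(codes[u.name] for u in pvars)
            probs = arr[(slice(None),) + pidx]  # (card, n)
        else:
            probs = np.repeat(arr[:, None], n, axis=1)
        cdf = np.cumsum(probs, axis=0)
        u01 = rng.random(n)
        codes[v.name] = np.minimum(
            (cdf < u01[None, :]).sum(axis=0), v.cardinality - 1
        )
    data = {
        v.name: np.asarray(v.states, dtype=object)[codes[v.name]]
        for v in net.variables
    }
    return pd.DataFrame(data, columns=[v.name for v in net.variables])
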