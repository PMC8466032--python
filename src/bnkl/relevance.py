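"""Relevance pruning and the min-weight elimination-ordering heuristic.

Two pruning rules are provided.  ``relevant_potentials`` keeps a CPT phi_i
exactly when X_i belongs to the query set Y or is an ancestor of a member
of Y; every other CPT is barren (it sums to one once its descendants are
eliminated), so the product of the retained CPTs marginalized onto Y equals
the full joint marginalized onto Y.  ``bayes_ball_relevant`` reaches the
same requisite set for the evidence-propagation engine by passing a
Bayes-ball over the query set {target} u evidence.  The engine needs the
unnormalized mass q(x_i) = p(x_i, evidence), not the posterior, so the
evidence variables are part of the query set and no ball is blocked by an
observation: potentials that would cancel in a normalized posterior (the
evidence's own priors) are genuinely required here.

Elimination orderings come from the greedy min-weight heuristic on the
interaction graph induced by the current potential scopes: repeatedly pick
the eliminable variable whose closed neighborhood has the smallest product
of cardinalities, connect its neighbors, and remove it.  Ties are broken
by the lowest global variable index, making the order deterministic.  Any
order yields the same numbers; only the operation counts differ.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from typing import Iterable, Literal, Sequence

from .network import BayesianNetwork
from .potentials import Variable

__all__ = [
    "InteractionGraph",
    "relevant_potentials",
    "bayes_ball_relevant",
    "min_weight_order",
]


class InteractionGraph:
    """Undirected adjacency induced by a collection of potential scopes."""

    def __init__(self, scopes: Iterable[Iterable[Variable]]):
        self.adj: dict[Variable, set[Variable]] = {}
        for scope in scopes:
            vs = list(scope)
            for v in vs:
                self.adj.setdefault(v, set())
            for a, b in combinations(set(vs), 2):
                self.adj[a].add(b)
                self.adj[b].add(a)

    @property
    def nodes(self) -> set[Variable]:
        return set(self.adj)

    def weight(self, v: Variable) -> int:
        """Product of cardinalities of v's closed neighborhood (clique size)."""
        w = v.cardinality
        for u in self.adj[v]:
            w *= u.cardinality
        return w

    def eliminate(self, v: Variable) -> None:
        """Remove v, connecting its neighbors (graph triangulation step)."""
        neigh = self.adj.pop(v)
        for u in neigh:
            self.adj[u].discard(v)
        for a, b in combinations(neigh, 2):
            self.adj[a].add(b)
            self.adj[b].add(a)


def min_weight_order(
    scopes: Sequence[Iterable[Variable]], eliminate: Iterable[Variable]
) -> list[Variable]:
    """Greedy min-weight elimination order for ``eliminate`` given ``scopes``."""
    g = InteractionGraph(scopes)
    remaining = set(eliminate)
    missing = remaining - g.nodes
    if missing:
        names = ", ".join(sorted(v.name for v in missing))
        raise ValueError(f"variables to eliminate not present in any scope: {names}")
    order: list[Variable] = []
    while remaining:
        v = min(remaining, key=lambda u: (g.weight(u), u.index, u.name))
        order.append(v)
        g.eliminate(v)
        remaining.remove(v)
    return order


def relevant_potentials(
    net: BayesianNetwork, query: Iterable[Variable]
) -> tuple[int, ...]:
    """Indices i of the CPTs relevant for the marginal on ``query``.

    phi_i is relevant iff X_i is in the query set or an ancestor of one of
    its members (the ancestral closure); the result is sorted and therefore
    independent of the query's iteration order.
    """
    q = tuple(query)
    rel = net.ancestors(q, include_self=True)
    return tuple(sorted(v.index for v in rel))


def _bayes_ball(
    net: BayesianNetwork,
    query: Iterable[Variable],
    observed: Iterable[Variable],
) -> set[Variable]:
    """Shachter's Bayes-ball traversal; returns the top-marked nodes.

    Top-marked nodes are exactly those whose CPTs are requisite for the
    joint of ``query`` given ``observed``.
    """
    obs = set(observed)
    g = net.graph()
    schedule: deque[tuple[Variable, Literal["child", "parent"]]] = deque(
        (v, "child") for v in query
    )
    top: set[Variable] = set()
    bottom: set[Variable] = set()
    while schedule:
        j, came_from = schedule.popleft()
        if came_from == "child":
            if j in obs:
                continue  # observed nodes block balls from children
            if j not in top:
                top.add(j)
                for p in g.predecessors(j):
                    schedule.append((p, "child"))
            if j not in bottom:
                bottom.add(j)
                for c in g.successors(j):
                    schedule.append((c, "parent"))
        else:  # ball arriving from a parent
            if j in obs:
                if j not in top:  # bounce back up
                    top.add(j)
                    for p in g.predecessors(j):
                        schedule.append((p, "child"))
            elif j not in bottom:
                bottom.add(j)
                for c in g.successors(j):
                    schedule.append((c, "parent"))
    return top


def bayes_ball_relevant(
    net: BayesianNetwork, target: Variable, evidence_vars: Iterable[Variable]
) -> tuple[int, ...]:
    """CPT indices requisite for q(x_target) = p(x_target, evidence).

    The evidence variables join the query set (their probability mass is
    part of the unnormalized q the propagation engine accumulates), so the
    ball starts from all of {target} u evidence with nothing observed; the
    result is never larger than the ancestral closure of that set.
    """
    ev = tuple(evidence_vars)
    if target in set(ev):
        raise ValueError(f"target {target.name!r} cannot also be evidence")
    if target not in net:
        raise KeyError(f"variable {target.name!r} not in network {net.name!r}")
    for v in ev:
        if v not in net:
            raise KeyError(f"variable {v.name!r} not in network {net.name!r}")
    top = _bayes_ball(net, (target,) + ev, observed=())
    return tuple(sorted(v.index for v in top))
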