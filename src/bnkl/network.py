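"""Bayesian network container: a DAG plus one CPT potential per family.

A network on variables X1..Xn stores, for each Xi, a conditional probability
table on the family f(Xi) = {Xi} u pa(Xi).  The joint distribution is the
product of all CPTs; ``joint()`` materializes it and is used only as the
enumeration oracle at desk scale (it is guarded by a state-space cap).

Two networks being compared must be defined on the same variable set with
identical state spaces; ``aligned_with`` rebuilds one network over the
other's Variable objects (matching by name) so that potentials from both
can be combined, and raises on any mismatch rather than harmonizing
silently.
"""

from __future__ import annotations

from collections import namedtuple
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .potentials import (
    IncompatiblePotentialError,
    Potential,
    ScopeError,
    Variable,
    canonical_scope,
)

__all__ = [
    "BayesianNetwork",
    "NetworkError",
    "VariableMismatchError",
    "StateSpaceError",
    "Violation",
]


class NetworkError(ValueError):
    """The network violates a structural or numerical invariant."""


class VariableMismatchError(NetworkError):
    """Two networks do not share an identical variable set / state spaces."""


class StateSpaceError(NetworkError):
    """The joint state space exceeds the enumeration cap."""


#: A validation finding: ``kind`` is one of "cycle", "scope", "values",
#: "normalization"; ``message`` is human-readable.
Violation = namedtuple("Violation", ["kind", "message"])

#: Default cap on joint table size for the enumeration oracle.
JOINT_CAP = 2**22


class BayesianNetwork:
    """Immutable-by-convention container for a discrete Bayesian network."""

    def __init__(
        self,
        variables: Sequence[Variable],
        parents: Mapping[Variable, Sequence[Variable]],
        cpts: Mapping[Variable, Potential],
        *,
        name: str = "network",
        check: bool = True,
    ):
        self.name = name
        self.variables = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise NetworkError("variable names must be unique within a network")
        for pos, v in enumerate(self.variables):
            if v.index != pos:
                raise NetworkError(
                    f"variable {v.name!r} has index {v.index}, expected its "
                    f"declaration position {pos}"
                )
        self._by_name = {v.name: v for v in self.variables}
        self.parents: dict[Variable, tuple[Variable, ...]] = {}
        for v in self.variables:
            ps = tuple(parents.get(v, ()))
            for p in ps:
                if p.name not in self._by_name or self._by_name[p.name] != p:
                    raise NetworkError(
                        f"parent {p.name!r} of {v.name!r} is not a network variable"
                    )
            self.parents[v] = ps
        missing = [v.name for v in self.variables if v not in cpts]
        if missing:
            raise NetworkError(f"missing CPTs for: {', '.join(missing)}")
        self.cpts = {v: cpts[v] for v in self.variables}
        self._graph: nx.DiGraph | None = None
        if check:
            self.check()

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_cpt_arrays(
        cls,
        states: Mapping[str, Sequence[str]],
        parents: Mapping[str, Sequence[str]],
        tables: Mapping[str, object],
        *,
        name: str = "network",
        check: bool = True,
    ) -> "BayesianNetwork":
        """Build a network from plain names and arrays.

        ``states`` maps each variable name to its state labels; insertion
        order fixes the declaration order (and hence variable indices).
        ``tables[child]`` has axes ``(child, parent1, parent2, ...)`` in the
        declared parent order, or is flat row-major over that shape.
        """
        variables = [
            Variable(n, tuple(s), i) for i, (n, s) in enumerate(states.items())
        ]
        by = {v.name: v for v in variables}
        parent_map: dict[Variable, tuple[Variable, ...]] = {}
        cpts: dict[Variable, Potential] = {}
        for v in variables:
            try:
                ps = tuple(by[p] for p in parents.get(v.name, ()))
            except KeyError as e:
                raise NetworkError(f"unknown parent {e.args[0]!r} of {v.name!r}") from None
            parent_map[v] = ps
            if v.name not in tables:
                raise NetworkError(f"missing CPT for {v.name!r}")
            shape = (v.cardinality,) + tuple(p.cardinality for p in ps)
            arr = np.asarray(tables[v.name], dtype=float)
            try:
                arr = arr.reshape(shape)
            except ValueError:
                raise NetworkError(
                    f"CPT for {v.name!r} has {arr.size} values, expected "
                    f"{int(np.prod(shape))}"
                ) from None
            cpts[v] = Potential((v,) + ps, arr, check=False)
        return cls(variables, parent_map, cpts, name=name, check=check)

    # ----------------------------------------------------------------- queries

    def __contains__(self, var: Variable) -> bool:
        return self._by_name.get(var.name) == var

    def __len__(self) -> int:
        return len(self.variables)

    def variable(self, name: str) -> Variable:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no variable named {name!r} in network {self.name!r}") from None

    def family(self, var: Variable) -> tuple[Variable, ...]:
        """The family f(Xi) = {Xi} u pa(Xi), in canonical scope order."""
        if var not in self:
            raise KeyError(f"variable {var.name!r} not in network {self.name!r}")
        return canonical_scope((var,) + self.parents[var])

    def graph(self) -> nx.DiGraph:
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.variables)
            for v, ps in self.parents.items():
                for p in ps:
                    g.add_edge(p, v)
            self._graph = g
        return self._graph

    @property
    def arcs(self) -> list[tuple[Variable, Variable]]:
        return [(p, v) for v in self.variables for p in self.parents[v]]

    @property
    def n_arcs(self) -> int:
        return sum(len(ps) for ps in self.parents.values())

    @property
    def n_parameters(self) -> int:
        """Total number of CPT entries (Table-5 style 'parameters' count)."""
        return sum(int(p.table.size) for p in self.cpts.values())

    def topological_order(self) -> list[Variable]:
        try:
            return list(
                nx.lexicographical_topological_sort(self.graph(), key=lambda v: v.index)
            )
        except nx.NetworkXUnfeasible:
            raise NetworkError(f"network {self.name!r} contains a directed cycle") from None

    def ancestors(self, of: Iterable[Variable], *, include_self: bool = False) -> set[Variable]:
        """Transitive parent closure of ``of`` (optionally including ``of``)."""
        targets = tuple(of)
        for v in targets:
            if v not in self:
                raise KeyError(f"variable {v.name!r} not in network {self.name!r}")
        g = self.graph()
        out: set[Variable] = set()
        for v in targets:
            out |= nx.ancestors(g, v)
        if include_self:
            out |= set(targets)
        return out

    # ------------------------------------------------------------------ oracle

    def joint(self, cap: int | None = JOINT_CAP) -> Potential:
        """The full joint distribution as one potential (enumeration oracle).

        Guarded by ``cap`` on the number of table entries because the joint
        is exponential in the number of variables.
        """
        size = 1
        for v in self.variables:
            size *= v.cardinality
        if cap is not None and size > cap:
            raise StateSpaceError(
                f"joint state space has {size} entries, above the cap of {cap}"
            )
        pot = Potential.unit()
        for v in self.variables:
            pot = pot * self.cpts[v]
        return pot

    # -------------------------------------------------------------- validation

    def validate(self, *, tol: float = 1e-9) -> list[Violation]:
        """Report (without raising) violations of the network invariants."""
        out: list[Violation] = []
        if not nx.is_directed_acyclic_graph(self.graph()):
            cyc = nx.find_cycle(self.graph())
            path = " -> ".join(e[0].name for e in cyc) + " -> " + cyc[-1][1].name
            out.append(Violation("cycle", f"directed cycle: {path}"))
        for v in self.variables:
            cpt = self.cpts[v]
            fam = canonical_scope((v,) + self.parents[v])
            if cpt.variables != fam:
                out.append(
                    Violation(
                        "scope",
                        f"CPT scope for {v.name!r} is "
                        f"({', '.join(u.name for u in cpt.variables)}), expected family "
                        f"({', '.join(u.name for u in fam)})",
                    )
                )
                continue
            if not np.all(np.isfinite(cpt.table)):
                out.append(Violation("values", f"CPT for {v.name!r} has non-finite values"))
                continue
            if np.any(cpt.table < 0):
                out.append(Violation("values", f"CPT for {v.name!r} has negative values"))
                continue
            ax = cpt.variables.index(v)
            colsums = cpt.table.sum(axis=ax)
            dev = float(np.max(np.abs(colsums - 1.0))) if colsums.size else 0.0
            if dev > tol:
                out.append(
                    Violation(
                        "normalization",
                        f"CPT for {v.name!r} deviates from column-stochastic by {dev:.3g}",
                    )
                )
        return out

    def check(self, *, tol: float = 1e-9) -> None:
        """Raise :class:`NetworkError` if any invariant is violated."""
        bad = self.validate(tol=tol)
        if bad:
            raise NetworkError("; ".join(v.message for v in bad))

    # -------------------------------------------------------------- comparison

    def same_variables(self, other: "BayesianNetwork") -> bool:
        if len(self) != len(other):
            return False
        for v in self.variables:
            o = other._by_name.get(v.name)
            if o is None or o.states != v.states:
                return False
        return True

    def aligned_with(self, reference: "BayesianNetwork") -> "BayesianNetwork":
        """Rebuild this network over ``reference``'s Variable objects.

        Variables are matched by name; declaration order (and hence the
        canonical scope order of every CPT) becomes the reference's.  Raises
        :class:`VariableMismatchError` if names or state spaces differ.
        """
        if set(self._by_name) != set(reference._by_name):
            only_a = sorted(set(self._by_name) - set(reference._by_name))
            only_b = sorted(set(reference._by_name) - set(self._by_name))
            raise VariableMismatchError(
                f"variable sets differ (only here: {only_a}; only in reference: {only_b})"
            )
        for v in self.variables:
            ref = reference._by_name[v.name]
            if ref.states != v.states:
                raise VariableMismatchError(
                    f"variable {v.name!r} has states {v.states} here but "
                    f"{ref.states} in the reference"
                )
        mapping = {v.name: reference._by_name[v.name] for v in self.variables}
        parents = {
            mapping[v.name]: tuple(mapping[p.name] for p in self.parents[v])
            for v in self.variables
        }
        cpts = {}
        for v in self.variables:
            old = self.cpts[v]
            new_scope = tuple(mapping[u.name] for u in old.variables)
            cpts[mapping[v.name]] = Potential(new_scope, old.table, check=False)
        return BayesianNetwork(
            reference.variables, parents, cpts, name=self.name, check=False
        )

    def equals(self, other: "BayesianNetwork") -> bool:
        """Exact structural and numerical equality (same declaration order)."""
        if self.variables != other.variables:
            return False
        for v in self.variables:
            if set(self.parents[v]) != set(other.parents[v]):
                return False
            if not self.cpts[v].equals(other.cpts[v]):
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"BayesianNetwork({self.name!r}, n={len(self)}, arcs={self.n_arcs}, "
            f"parameters={self.n_parameters})"
        )
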