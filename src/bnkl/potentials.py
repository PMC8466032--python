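"""Discrete potential algebra: tables over configurations of finite variables.

A *potential* phi assigns a nonnegative real number to every joint
configuration of an ordered set of discrete variables (its *scope*).
Conditional probability tables of a Bayesian network are potentials on the
family {X_i} u pa(X_i); products, marginals and evidence restrictions of
potentials are again potentials.  Three operations generate everything the
inference engines need:

* multiplication  -- pointwise product on the union of the two scopes,
* marginalization -- summing out scope variables,
* selection       -- slicing the table at an observed configuration.

Scopes are always kept in a canonical order (ascending global variable
index, then name), so two potentials on the same variables store their
tables with identical axis order.  Potential equality checks, the planner's
cache keys and the brute-force joint comparisons all rely on this.

Values are stored in linear space; log-space accumulation happens only in
the divergence layer, so the algebra here matches the textbook operation
contracts exactly (e.g. summing a CPT over its child variable yields the
all-ones table).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Variable",
    "Potential",
    "ScopeError",
    "IncompatiblePotentialError",
    "canonical_scope",
    "project",
    "iter_configurations",
]


class ScopeError(KeyError):
    """A variable was required from a scope or configuration that lacks it."""


class IncompatiblePotentialError(ValueError):
    """Two potentials (or scope members) disagree on a shared variable's states."""


@dataclass(frozen=True)
class Variable:
    """A discrete random variable with named states.

    ``index`` is the variable's position in its network's declaration order.
    It defines the canonical sort order of scopes and the tie-breaking rule
    of the elimination heuristics; state indices are 0-based regardless of
    the labels used by file formats.
    """

    name: str
    states: tuple[str, ...]
    index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 1:
            raise ValueError(f"variable {self.name!r} needs at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def sort_key(self) -> tuple[int, str]:
        return (self.index, self.name)

    def __repr__(self) -> str:  # compact: X2[3]
        return f"{self.name}[{self.cardinality}]"


# A configuration is a plain mapping Variable -> 0-based state index.
Configuration = Mapping[Variable, int]


def canonical_scope(variables: Iterable[Variable]) -> tuple[Variable, ...]:
    """Sort ``variables`` into canonical order, rejecting duplicates.

    Raises :class:`ScopeError` on a duplicated variable and
    :class:`IncompatiblePotentialError` if two distinct variables share a
    name (which would make the scope ambiguous).
    """
    vs = tuple(variables)
    seen: dict[str, Variable] = {}
    for v in vs:
        prev = seen.get(v.name)
        if prev is None:
            seen[v.name] = v
        elif prev == v:
            raise ScopeError(f"duplicate variable {v.name!r} in scope")
        else:
            raise IncompatiblePotentialError(
                f"two different variables named {v.name!r} in one scope"
            )
    return tuple(sorted(vs, key=Variable.sort_key))


def project(config: Configuration, scope: Iterable[Variable]) -> dict[Variable, int]:
    """Restrict a configuration to ``scope`` (the x -> x|Y projection)."""
    out: dict[Variable, int] = {}
    for v in scope:
        if v not in config:
            raise ScopeError(f"configuration does not assign variable {v.name!r}")
        out[v] = config[v]
    return out


def iter_configurations(scope: Iterable[Variable]) -> Iterator[dict[Variable, int]]:
    """Iterate all configurations of ``scope`` in canonical row-major order."""
    canon = canonical_scope(scope)
    for idx in itertools.product(*(range(v.cardinality) for v in canon)):
        yield dict(zip(canon, idx))


class Potential:
    """A nonnegative real table over all configurations of its scope.

    The scope given to the constructor may be in any order; it is sorted
    canonically and the table axes are permuted to match.  An empty scope is
    a first-class scalar (0-dimensional table).
    """

    __slots__ = ("variables", "table", "_vset")

    def __init__(self, variables: Iterable[Variable], table, *, check: bool = True):
        given = tuple(variables)
        canon = canonical_scope(given)
        arr = np.asarray(table, dtype=float)
        expected = tuple(v.cardinality for v in given)
        if arr.shape != expected:
            size = 1
            for c in expected:
                size *= c
            if arr.ndim == 1 and arr.size == size:
                arr = arr.reshape(expected)
            else:
                raise ValueError(
                    f"table shape {arr.shape} does not match scope cardinalities {expected}"
                )
        if canon != given:
            perm = [given.index(v) for v in canon]
            arr = np.transpose(arr, perm)
        if check:
            if not np.all(np.isfinite(arr)):
                raise ValueError("potential table contains non-finite values")
            if np.any(arr < 0):
                raise ValueError("potential table contains negative values")
        self.variables = canon
        self.table = arr
        self._vset = frozenset(canon)

    # ------------------------------------------------------------------ basics

    @classmethod
    def unit(cls) -> "Potential":
        """The multiplicative identity: a scalar potential of value 1."""
        return cls((), 1.0, check=False)

    @property
    def scope_set(self) -> frozenset[Variable]:
        return self._vset

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(v.cardinality for v in self.variables)

    def total(self) -> float:
        return float(self.table.sum())

    def copy(self) -> "Potential":
        return Potential(self.variables, self.table.copy(), check=False)

    def __call__(self, config: Configuration) -> float:
        idx = []
        for v in self.variables:
            if v not in config:
                raise ScopeError(f"configuration does not assign variable {v.name!r}")
            idx.append(config[v])
        return float(self.table[tuple(idx)])

    def __repr__(self) -> str:
        names = ",".join(v.name for v in self.variables) or "-"
        return f"Potential({names}; total={self.total():.6g})"

    # -------------------------------------------------------------- operations

    def _aligned(self, out_vars: tuple[Variable, ...]) -> np.ndarray:
        """View of the table broadcastable over ``out_vars`` (a superset scope)."""
        shape = tuple(v.cardinality if v in self._vset else 1 for v in out_vars)
        return self.table.reshape(shape)

    def __mul__(self, other: "Potential") -> "Potential":
        if not isinstance(other, Potential):
            return NotImplemented
        merged: dict[str, Variable] = {}
        for v in self.variables + other.variables:
            prev = merged.get(v.name)
            if prev is None:
                merged[v.name] = v
            elif prev != v:
                raise IncompatiblePotentialError(
                    f"shared variable {v.name!r} has mismatched state spaces"
                )
        out_vars = tuple(sorted(merged.values(), key=Variable.sort_key))
        arr = self._aligned(out_vars) * other._aligned(out_vars)
        return Potential(out_vars, arr, check=False)

    def sum_out(self, var: Variable) -> "Potential":
        """Remove ``var`` by summation (phi^{-X}); conserves total mass."""
        if var not in self._vset:
            raise ScopeError(f"variable {var.name!r} not in scope")
        ax = self.variables.index(var)
        keep = tuple(v for v in self.variables if v != var)
        return Potential(keep, self.table.sum(axis=ax), check=False)

    def marginalize(self, scope: Iterable[Variable]) -> "Potential":
        """Marginalize onto ``scope`` (phi|Z); removal-order invariant."""
        target = canonical_scope(scope)
        tset = set(target)
        if not tset <= self._vset:
            missing = ", ".join(sorted(v.name for v in tset - self._vset))
            raise ScopeError(f"marginalization target not within scope: {missing}")
        axes = tuple(i for i, v in enumerate(self.variables) if v not in tset)
        if not axes:
            return self
        keep = tuple(v for v in self.variables if v in tset)
        return Potential(keep, self.table.sum(axis=axes), check=False)

    def restrict(self, config: Configuration) -> "Potential":
        """Selection phi^{Z=z}: slice at the configured values.

        Variables of ``config`` outside the scope are ignored; if the overlap
        is empty the potential is returned unchanged.
        """
        idx: list = []
        keep: list[Variable] = []
        for v in self.variables:
            if v in config:
                s = config[v]
                if not 0 <= s < v.cardinality:
                    raise ValueError(
                        f"state index {s} out of range for variable {v.name!r}"
                    )
                idx.append(s)
            else:
                idx.append(slice(None))
                keep.append(v)
        if len(keep) == len(self.variables):
            return self
        return Potential(tuple(keep), self.table[tuple(idx)], check=False)

    # ------------------------------------------------------------- comparisons

    def equals(self, other: "Potential") -> bool:
        return self.variables == other.variables and np.array_equal(
            self.table, other.table
        )

    def allclose(self, other: "Potential", *, rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return self.variables == other.variables and np.allclose(
            self.table, other.table, rtol=rtol, atol=atol
        )
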