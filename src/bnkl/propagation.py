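"""Evidence-propagation engine: one elimination run per parent configuration.

The expected log-likelihood LL(NA, NB) = sum_x pA(x) log pB(x) decomposes
over NB's families into terms log(phi_i^B(x_i, x_pa)) weighted by the
family marginals of pA.  This engine obtains each weight by a separate
variable-elimination run in NA: fix a parent configuration x_pa as
evidence, prune irrelevant CPTs (Bayes-ball), restrict the survivors to
the evidence, and delete every variable except the target X_i.  The
product of the remaining potentials is the unnormalized q with
q(x_i) = pA(x_i, x_pa); no normalization is performed because the
evidence mass is exactly what the decomposition requires.

The number of elimination runs for one LL term is
sum_i prod_{X_j in pa_B(X_i)} n_j -- one run per variable per parent
configuration -- which is why the cached engine pays off on dense
networks.
"""

from __future__ import annotations

import math
import warnings
from functools import reduce
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import BayesianNetwork
from .potentials import Potential, Variable, canonical_scope, iter_configurations
from .relevance import bayes_ball_relevant, min_weight_order

__all__ = [
    "ZeroProbabilityError",
    "ZeroProbabilityWarning",
    "delete_variable",
    "marginal_given_parent_config",
    "ll_propagation",
    "ll_propagation_with_runs",
    "expected_run_count",
]


class ZeroProbabilityError(ValueError):
    """Positive mass placed where the approximating network has probability 0."""


class ZeroProbabilityWarning(UserWarning):
    """The divergence is +infinity because of a structural zero in NB."""


_LN2 = math.log(2.0)


def log_scale(log_base) -> float:
    """Natural-log divisor for the requested base ('e' or 2)."""
    if log_base in ("e", math.e):
        return 1.0
    if log_base in (2, "2"):
        return _LN2
    raise ValueError(f"unsupported log base {log_base!r} (use 'e' or 2)")


def xlogy_sum(mass: np.ndarray, values: np.ndarray, zero_policy: str, context: str = "") -> float:
    """sum(mass * log(values)) in nats with the 0*log(0) := 0 convention.

    Where mass > 0 but values == 0 the term is -infinity: under the default
    "extended" policy a structured warning is emitted and -inf returned;
    under "strict" a :class:`ZeroProbabilityError` is raised.
    """
    if zero_policy not in ("extended", "strict"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    mass = np.asarray(mass, dtype=float)
    values = np.asarray(values, dtype=float)
    m = mass > 0
    if np.any(values[m] == 0):
        msg = (
            "probability mass assigned to a configuration with zero probability"
            + (f" ({context})" if context else "")
        )
        if zero_policy == "strict":
            raise ZeroProbabilityError(msg)
        warnings.warn(msg + "; log-likelihood is -inf", ZeroProbabilityWarning, stacklevel=3)
        return float("-inf")
    return float(np.sum(mass[m] * np.log(values[m])))


def delete_variable(
    potentials: Iterable[Potential], var: Variable, *, warn: bool = True
) -> list[Potential]:
    """One variable-elimination step on a factor set.

    Combines (in current collection order) all potentials mentioning
    ``var``, sums ``var`` out of the product, and returns the updated
    collection.  The product over the collection is invariant up to the
    summation: prod(result) == (prod(input)) with ``var`` removed.
    """
    pots = list(potentials)
    mentioning = [p for p in pots if var in p.scope_set]
    if not mentioning:
        if warn:
            warnings.warn(f"no potential mentions {var.name!r}; deletion is a no-op")
        return pots
    product = reduce(lambda a, b: a * b, mentioning)
    rest = [p for p in pots if var not in p.scope_set]
    rest.append(product.sum_out(var))
    return rest


def marginal_given_parent_config(
    na: BayesianNetwork,
    target: Variable,
    parent_config: Mapping[Variable, int],
) -> Potential:
    """Unnormalized q on {target} with q(x) = pA(x, parent_config).

    Pruning (Bayes-ball) precedes evidence restriction; then every variable
    other than the target is deleted in min-weight order and the surviving
    potentials are multiplied.
    """
    evidence_vars = tuple(parent_config)
    rel = bayes_ball_relevant(na, target, evidence_vars)
    pots = [na.cpts[na.variables[i]].restrict(parent_config) for i in rel]
    union: set[Variable] = set()
    for p in pots:
        union |= p.scope_set
    order = min_weight_order([p.variables for p in pots], union - {target})
    for v in order:
        pots = delete_variable(pots, v, warn=False)
    q = reduce(lambda a, b: a * b, pots, Potential.unit())
    if q.variables != (target,):
        raise RuntimeError(
            f"elimination left scope ({', '.join(v.name for v in q.variables)}), "
            f"expected ({target.name})"
        )
    return q


def expected_run_count(nb: BayesianNetwork) -> int:
    """sum_i prod_{X_j in pa(X_i)} n_j: elimination runs for one LL pass."""
    total = 0
    for v in nb.variables:
        runs = 1
        for p in nb.parents[v]:
            runs *= p.cardinality
        total += runs
    return total


def ll_propagation_with_runs(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    zero_policy: str = "extended",
) -> tuple[float, int]:
    """LL(NA, NB) in nats plus the number of elimination runs performed."""
    nb = nb.aligned_with(na)
    total = 0.0
    runs = 0
    for v in nb.variables:
        cpt = nb.cpts[v]
        pvars = canonical_scope(nb.parents[v])
        for xpa in iter_configurations(pvars):
            q = marginal_given_parent_config(na, v, xpa)
            runs += 1
            cond = cpt.restrict(xpa)  # potential on {v}
            total += xlogy_sum(
                q.table, cond.table, zero_policy, context=f"family of {v.name}"
            )
    return total, runs


def ll_propagation(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    log_base="e",
    zero_policy: str = "extended",
) -> float:
    """Expected log-likelihood LL(NA, NB) via evidence propagation."""
    nats, _ = ll_propagation_with_runs(na, nb, zero_policy=zero_policy)
    return nats / log_scale(log_base)
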