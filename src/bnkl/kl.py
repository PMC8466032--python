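"""Kullback-Leibler divergence between two Bayesian networks.

For networks NA (reference) and NB (approximation) on the same variables,

    KL(NA, NB) = sum_x pA(x) log(pA(x) / pB(x))
               = LL(NA, NA) - LL(NA, NB),

where LL(p, q) = sum_x p(x) log q(x) is the expected log-likelihood.  LL
decomposes over the approximating network's families:

    LL(NA, NB) = sum_i sum_{x_fi} log(phi_i^B(x_fi)) * (pA)|fi(x_fi),

so the whole computation reduces to the family marginals of pA on NB's
families (for the cross term) and on NA's own families (for the entropy
term).  Both sets of marginals come from the same reference network, which
is exactly why the shared operation cache pays off: ``kl_cached`` plans
them in one batch.

Three engines are provided: ``brute_force_kl`` (joint enumeration, the
desk-scale oracle), ``kl_propagation`` (one elimination run per variable
and parent configuration) and ``kl_cached`` (symbolic planning with
repositories).  All agree to numerical precision; they differ only in
cost.

Zero probabilities: 0*log(0) is always taken as 0.  Where pA puts mass on
a configuration with pB = 0 the divergence is +infinity; the default
"extended" policy returns inf with a structured warning, "strict" raises.
The default log base is e (nats), with base 2 available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cached import PlanStats, QueryPlan, family_query_set, plan_marginals
from .network import BayesianNetwork, JOINT_CAP
from .potentials import Potential, ScopeError, Variable
from .propagation import (
    ZeroProbabilityError,
    ZeroProbabilityWarning,
    ll_propagation_with_runs,
    log_scale,
    xlogy_sum,
)

__all__ = [
    "KLResult",
    "ll_from_marginals",
    "kl_cached",
    "kl_propagation",
    "brute_force_ll",
    "brute_force_kl",
]


@dataclass(frozen=True)
class KLResult:
    """Divergence plus its two log-likelihood terms and engine diagnostics.

    ``kl == ll_self - ll_cross`` by construction; ``stats`` carries the
    ops/rep/del counters for the cached engine, ``runs`` the number of
    elimination runs for the propagation engine.  ``plan`` (optional) is
    the executed :class:`QueryPlan` when the caller asked to keep it.
    """

    kl: float
    ll_self: float
    ll_cross: float
    engine: str
    log_base: object = "e"
    stats: PlanStats | None = None
    runs: int | None = None
    plan: QueryPlan | None = None

    def summary(self) -> str:
        lines = [
            f"engine    : {self.engine}",
            f"KL        : {self.kl:.12g}",
            f"LL(A,A)   : {self.ll_self:.12g}",
            f"LL(A,B)   : {self.ll_cross:.12g}",
            f"log base  : {self.log_base}",
        ]
        if self.stats is not None:
            lines.append(
                f"ops/rep/del: {self.stats.ops}/{self.stats.rep}/{self.stats.dels}"
            )
        if self.runs is not None:
            lines.append(f"runs      : {self.runs}")
        return "\n".join(lines)


def ll_from_marginals(
    net: BayesianNetwork,
    marginals: Mapping[Variable, Potential],
    *,
    log_base="e",
    zero_policy: str = "extended",
) -> float:
    """Assemble LL(., net) from one reference marginal per family of ``net``.

    ``marginals[v]`` must be a potential on exactly the family of ``v``;
    terms with zero marginal mass contribute nothing regardless of the CPT
    value.
    """
    total = 0.0
    for v in net.variables:
        fam = net.family(v)
        m = marginals[v]
        if m.variables != fam:
            raise ScopeError(
                f"marginal for {v.name!r} has scope "
                f"({', '.join(u.name for u in m.variables)}), expected family "
                f"({', '.join(u.name for u in fam)})"
            )
        total += xlogy_sum(
            m.table, net.cpts[v].table, zero_policy, context=f"family of {v.name}"
        )
    return total / log_scale(log_base)


def kl_cached(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    log_base="e",
    zero_policy: str = "extended",
    elimination_order=None,
    keep_plan: bool = False,
) -> KLResult:
    """KL(NA, NB) with the cached variable-elimination engine.

    Plans the union of both networks' family marginals once over NA,
    executes the plan, and evaluates the LL decomposition twice (with NA's
    CPTs for the entropy term and NB's for the cross term).
    """
    nb = nb.aligned_with(na)
    queries, qmap = family_query_set(na, nb)
    plan = plan_marginals(na, queries, elimination_order=elimination_order)
    margs = plan.execute()
    m_self = {v: margs[qmap[("A", v.name)]] for v in na.variables}
    m_cross = {v: margs[qmap[("B", v.name)]] for v in nb.variables}
    ll_self = ll_from_marginals(na, m_self, log_base="e", zero_policy=zero_policy)
    ll_cross = ll_from_marginals(nb, m_cross, log_base="e", zero_policy=zero_policy)
    scale = log_scale(log_base)
    return KLResult(
        kl=(ll_self - ll_cross) / scale,
        ll_self=ll_self / scale,
        ll_cross=ll_cross / scale,
        engine="cache",
        log_base=log_base,
        stats=plan.stats(),
        plan=plan if keep_plan else None,
    )


def kl_propagation(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    log_base="e",
    zero_policy: str = "extended",
) -> KLResult:
    """KL(NA, NB) with the evidence-propagation engine (no cache)."""
    nb = nb.aligned_with(na)
    ll_self, runs_self = ll_propagation_with_runs(na, na, zero_policy=zero_policy)
    ll_cross, runs_cross = ll_propagation_with_runs(na, nb, zero_policy=zero_policy)
    scale = log_scale(log_base)
    return KLResult(
        kl=(ll_self - ll_cross) / scale,
        ll_self=ll_self / scale,
        ll_cross=ll_cross / scale,
        engine="propagation",
        log_base=log_base,
        runs=runs_self + runs_cross,
    )


def brute_force_ll(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    log_base="e",
    zero_policy: str = "extended",
    cap: int | None = JOINT_CAP,
) -> float:
    """LL(NA, NB) by full joint enumeration (oracle; capped state space)."""
    nb = nb.aligned_with(na)
    pa = na.joint(cap).table.ravel()
    pb = nb.joint(cap).table.ravel()
    return xlogy_sum(pa, pb, zero_policy, context="joint enumeration") / log_scale(
        log_base
    )


def brute_force_kl(
    na: BayesianNetwork,
    nb: BayesianNetwork,
    *,
    log_base="e",
    zero_policy: str = "extended",
    cap: int | None = JOINT_CAP,
) -> float:
    """KL(NA, NB) by full joint enumeration (oracle; capped state space)."""
    nb = nb.aligned_with(na)
    pa = na.joint(cap).table.ravel()
    pb = nb.joint(cap).table.ravel()
    m = pa > 0
    if np.any(pb[m] == 0):
        msg = "reference mass on a configuration with zero approximating probability"
        if zero_policy == "strict":
            raise ZeroProbabilityError(msg)
        if zero_policy != "extended":
            raise ValueError(f"unknown zero policy {zero_policy!r}")
        warnings.warn(msg + "; KL is +inf", ZeroProbabilityWarning, stacklevel=2)
        return float("inf")
    if zero_policy not in ("extended", "strict"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    return float(np.sum(pa[m] * (np.log(pa[m]) - np.log(pb[m])))) / log_scale(log_base)
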