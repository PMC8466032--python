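"""Cached variable-elimination engine with symbolic operation planning.

All family marginals needed for the divergence are computed in one shot.
The planner runs variable elimination *symbolically* (scopes only, no
tables) over an ordered list of queries Y1..YK, recording every
combination and marginalization as a register in an operation repository
(R_O) keyed by its arguments.  When a later query requests an operation
already registered, the existing result is reused -- a cache hit -- and
only the time stamps are refreshed.  Potentials live in a potential
repository (R_Phi); each entry carries the clock value of the last
operation that needs it, with -1 protecting query results from deletion.

The planner clock t starts at 1 and increments after every conditional
call, hits included; a register's id is the clock value at its creation,
so ids may skip values wherever a hit consumed a tick.

The execution pass then walks the clock: the register with id t (if any)
is computed numerically -- each register exactly once -- and every
repository entry whose time stamp equals t is reclaimed, so peak memory
follows the planned lifetimes and, at the end, only the protected query
results remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .network import BayesianNetwork, VariableMismatchError
from .potentials import Potential, Variable, canonical_scope
from .relevance import min_weight_order, relevant_potentials

__all__ = [
    "COMBINATION",
    "MARGINALIZATION",
    "PotentialEntry",
    "OperationRegister",
    "CacheHit",
    "PlanStats",
    "QueryPlan",
    "plan_marginals",
    "family_query_set",
    "RepositoryError",
    "PlanningBugError",
]

COMBINATION = "comb"
MARGINALIZATION = "marg"

#: Time stamp protecting a repository entry from deletion.
PROTECTED = -1


class RepositoryError(KeyError):
    """An operation referenced a potential id absent from the repository."""


class PlanningBugError(RuntimeError):
    """Execution needed a potential the planner had already reclaimed."""


@dataclass
class PotentialEntry:
    """R_Phi entry: scope is known from planning; the table only at execution."""

    id: int
    variables: tuple[Variable, ...]
    time: int

    @property
    def size(self) -> int:
        n = 1
        for v in self.variables:
            n *= v.cardinality
        return n


@dataclass(frozen=True)
class OperationRegister:
    """R_O entry (id, type, arg1, arg2, result).

    For a marginalization ``arg2`` is the index of the removed variable.
    ``query_index`` is the 1-based query k during which the register was
    created (bookkeeping; not part of the cache key).
    """

    id: int
    type: str
    arg1: int
    arg2: int
    result: int
    query_index: int


@dataclass(frozen=True)
class CacheHit:
    """A conditional call satisfied from R_O at clock ``t`` during query k."""

    t: int
    query_index: int
    register: OperationRegister


@dataclass(frozen=True)
class PlanStats:
    """Operation counters in the reporting convention of the benchmark tables.

    ops: registers stored in R_O (numeric operations actually executed);
    rep: conditional calls answered from the cache;
    dels: potentials reclaimed from R_Phi during execution;
    cond_calls: total conditional calls (== ops + rep);
    executed: numeric operations performed (== ops, each register once).
    """

    ops: int
    rep: int
    dels: int
    cond_calls: int
    executed: int


OrderFn = Callable[[Sequence[tuple[Variable, ...]], Iterable[Variable]], list[Variable]]


class QueryPlan:
    """A planned (and then executed) batch of marginal queries on one network."""

    def __init__(self, network: BayesianNetwork, queries: Sequence[Iterable[Variable]]):
        self.network = network
        self.queries: tuple[tuple[Variable, ...], ...] = tuple(
            canonical_scope(q) for q in queries
        )
        for q in self.queries:
            for v in q:
                if v not in network:
                    raise KeyError(
                        f"query variable {v.name!r} not in network {network.name!r}"
                    )
        self.entries: dict[int, PotentialEntry] = {}
        self.registers: list[OperationRegister] = []
        self.result_ids: list[int] = []
        self.hits: list[CacheHit] = []
        self.cond_calls = 0
        self.clock_end = 0
        self._key2reg: dict[tuple, OperationRegister] = {}
        self._next_pid = len(network) + 1
        self._executed = False
        self._dels = 0
        self._executed_ops = 0
        self._results: list[Potential] | None = None

    # ------------------------------------------------------------- repositories

    def _cpt_id(self, var: Variable) -> int:
        return var.index + 1

    def _entry(self, pid: int) -> PotentialEntry:
        try:
            return self.entries[pid]
        except KeyError:
            raise RepositoryError(f"no potential with id {pid} in the repository") from None

    def _update_time(self, pid: int, t: int) -> None:
        e = self._entry(pid)
        if e.time != PROTECTED:
            e.time = t

    def _cond_scombine(self, a: int, b: int, t: int, k: int) -> int:
        """Conditional symbolic combination; returns the result potential id."""
        self.cond_calls += 1
        key = (COMBINATION, a, b)
        reg = self._key2reg.get(key)
        if reg is not None:
            self.hits.append(CacheHit(t, k, reg))
            self._update_time(a, t)
            self._update_time(b, t)
            self._update_time(reg.result, t)
            return reg.result
        scope = canonical_scope(
            dict.fromkeys(self._entry(a).variables + self._entry(b).variables)
        )
        rid = self._next_pid
        self._next_pid += 1
        self.entries[rid] = PotentialEntry(rid, scope, t)
        reg = OperationRegister(t, COMBINATION, a, b, rid, k)
        self.registers.append(reg)
        self._key2reg[key] = reg
        self._update_time(a, t)
        self._update_time(b, t)
        return rid

    def _cond_smarginalize(self, a: int, var_index: int, t: int, k: int) -> int:
        """Conditional symbolic marginalization removing one variable."""
        self.cond_calls += 1
        key = (MARGINALIZATION, a, var_index)
        reg = self._key2reg.get(key)
        if reg is not None:
            self.hits.append(CacheHit(t, k, reg))
            self._update_time(a, t)
            self._update_time(reg.result, t)
            return reg.result
        var = self.network.variables[var_index]
        scope = tuple(v for v in self._entry(a).variables if v != var)
        rid = self._next_pid
        self._next_pid += 1
        self.entries[rid] = PotentialEntry(rid, scope, t)
        reg = OperationRegister(t, MARGINALIZATION, a, var_index, rid, k)
        self.registers.append(reg)
        self._key2reg[key] = reg
        self._update_time(a, t)
        return rid

    # ----------------------------------------------------------------- planning

    def _build(self, order_fn: OrderFn) -> None:
        net = self.network
        for v in net.variables:
            fam = net.family(v)
            self.entries[self._cpt_id(v)] = PotentialEntry(self._cpt_id(v), fam, 0)
        t = 1
        for k, query in enumerate(self.queries, start=1):
            rel = relevant_potentials(net, query)
            current = sorted(self._cpt_id(net.variables[i]) for i in rel)
            union: set[Variable] = set()
            for pid in current:
                union |= set(self.entries[pid].variables)
            to_remove = union - set(query)
            order = order_fn([self.entries[pid].variables for pid in current], to_remove)
            for var in order:
                mentioning = [
                    pid for pid in current if var in set(self.entries[pid].variables)
                ]
                psi = mentioning[0]
                for other in mentioning[1:]:
                    psi = self._cond_scombine(psi, other, t, k)
                    t += 1
                psi = self._cond_smarginalize(psi, var.index, t, k)
                t += 1
                current = sorted((set(current) - set(mentioning)) | {psi})
            psi_k = current[0]
            for pid in current[1:]:
                psi_k = self._cond_scombine(psi_k, pid, t, k)
                t += 1
            self.result_ids.append(psi_k)
            self.entries[psi_k].time = PROTECTED
        self.clock_end = t - 1

    # ---------------------------------------------------------------- execution

    def execute(self) -> list[Potential]:
        """Run the planned registers numerically, in id order, once each.

        After the step at clock t every repository entry stamped t is
        reclaimed; on return only protected (time -1) entries survive.
        Returns the K query marginals, in query order.
        """
        if self._executed:
            raise RuntimeError("plan has already been executed")
        net = self.network
        live: dict[int, Potential] = {}
        for v in net.variables:
            e = self.entries[self._cpt_id(v)]
            if e.time != 0:  # time 0 = never needed by any query
                cpt = net.cpts[v]
                live[e.id] = Potential(cpt.variables, cpt.table.copy(), check=False)
        regs_by_id = {r.id: r for r in self.registers}
        dels = 0
        executed = 0
        for t in range(1, self.clock_end + 1):
            reg = regs_by_id.get(t)
            if reg is not None:
                a = live.get(reg.arg1)
                if a is None:
                    raise PlanningBugError(
                        f"register {reg.id} needs potential {reg.arg1}, already reclaimed"
                    )
                if reg.type == COMBINATION:
                    b = live.get(reg.arg2)
                    if b is None:
                        raise PlanningBugError(
                            f"register {reg.id} needs potential {reg.arg2}, already reclaimed"
                        )
                    res = a * b
                else:
                    res = a.sum_out(net.variables[reg.arg2])
                if res.variables != self.entries[reg.result].variables:
                    raise PlanningBugError(
                        f"register {reg.id} produced scope "
                        f"{[v.name for v in res.variables]}, planner expected "
                        f"{[v.name for v in self.entries[reg.result].variables]}"
                    )
                live[reg.result] = res
                executed += 1
            expired = [pid for pid in live if self.entries[pid].time == t]
            for pid in expired:
                del live[pid]
                dels += 1
        results = []
        for pid in self.result_ids:
            pot = live.get(pid)
            if pot is None:
                raise PlanningBugError(f"query result potential {pid} was reclaimed")
            results.append(pot)
        stray = [pid for pid in live if self.entries[pid].time != PROTECTED]
        if stray:
            raise PlanningBugError(f"unprotected potentials survived execution: {stray}")
        self._executed = True
        self._dels = dels
        self._executed_ops = executed
        self._results = results
        return list(results)

    @property
    def executed(self) -> bool:
        return self._executed

    def results(self) -> list[Potential]:
        if self._results is None:
            raise RuntimeError("execute the plan before asking for its results")
        return list(self._results)

    def stats(self) -> PlanStats:
        if not self._executed:
            raise RuntimeError("execute the plan before reading its statistics")
        return PlanStats(
            ops=len(self.registers),
            rep=len(self.hits),
            dels=self._dels,
            cond_calls=self.cond_calls,
            executed=self._executed_ops,
        )

    # ------------------------------------------------------------------- export

    def _pname(self, pid: int) -> str:
        return f"phi_{pid}"

    def dump(self) -> str:
        """Plain-text trace of both repositories (debugging / worked examples)."""
        lines = ["Potential repository (R_Phi)", f"{'id':>4}  {'scope':<24} time"]
        for pid in sorted(self.entries):
            e = self.entries[pid]
            scope = "(" + ", ".join(v.name for v in e.variables) + ")"
            lines.append(f"{pid:>4}  {scope:<24} {e.time}")
        lines.append("")
        lines.append("Operation repository (R_O)")
        lines.append(f"{'id':>4}  {'type':<5} {'arg1':<7} {'arg2':<7} result")
        for r in self.registers:
            arg2 = (
                self._pname(r.arg2)
                if r.type == COMBINATION
                else self.network.variables[r.arg2].name
            )
            lines.append(
                f"{r.id:>4}  {r.type:<5} {self._pname(r.arg1):<7} {arg2:<7} "
                f"{self._pname(r.result)}"
            )
        lines.append("")
        lines.append(
            "results: " + ", ".join(self._pname(pid) for pid in self.result_ids)
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready dump of R_Phi, R_O, the result list and the counters."""
        out = {
            "queries": [[v.name for v in q] for q in self.queries],
            "potentials": [
                {
                    "id": e.id,
                    "scope": [v.name for v in e.variables],
                    "time": e.time,
                }
                for e in (self.entries[pid] for pid in sorted(self.entries))
            ],
            "operations": [
                {
                    "id": r.id,
                    "type": r.type,
                    "arg1": r.arg1,
                    "arg2": r.arg2,
                    "result": r.result,
                    "query": r.query_index,
                }
                for r in self.registers
            ],
            "hits": [
                {"t": h.t, "query": h.query_index, "register": h.register.id}
                for h in self.hits
            ],
            "results": list(self.result_ids),
        }
        if self._executed:
            s = self.stats()
            out["stats"] = {
                "ops": s.ops,
                "rep": s.rep,
                "del": s.dels,
                "cond_calls": s.cond_calls,
                "executed": s.executed,
            }
        return out


def plan_marginals(
    network: BayesianNetwork,
    queries: Sequence[Iterable[Variable]],
    *,
    elimination_order: OrderFn | None = None,
) -> QueryPlan:
    """Symbolically plan the marginals of ``network`` on each query set.

    For each query: select the relevant CPTs (ancestral rule), eliminate
    the out-of-query variables in the given order (min-weight by default),
    combining the potentials that mention each variable pairwise in
    ascending repository-id order, then combine the survivors into the
    query result.  No numeric tables are touched; call
    :meth:`QueryPlan.execute` for the numbers.
    """
    plan = QueryPlan(network, queries)
    plan._build(elimination_order or min_weight_order)
    return plan


def family_query_set(
    na: BayesianNetwork, nb: BayesianNetwork
) -> tuple[list[tuple[Variable, ...]], dict[tuple[str, str], int]]:
    """The ordered query sets for a KL computation, duplicates collapsed.

    Queries are NA's families in variable order, then NB's; a family seen
    twice keeps its first position.  The returned map sends
    ``("A", variable_name)`` / ``("B", variable_name)`` to the index of the
    query holding that family's marginal.
    """
    if nb.variables != na.variables:
        raise VariableMismatchError(
            "networks must share identical variable objects; align them first"
        )
    queries: list[tuple[Variable, ...]] = []
    qmap: dict[tuple[str, str], int] = {}
    seen: dict[tuple[int, ...], int] = {}
    for tag, net in (("A", na), ("B", nb)):
        for v in net.variables:
            fam = net.family(v)
            key = tuple(u.index for u in fam)
            if key not in seen:
                seen[key] = len(queries)
                queries.append(fam)
            qmap[(tag, v.name)] = seen[key]
    return queries, qmap
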