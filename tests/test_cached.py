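"""Cached engine: worked-example repository traces, accounting, execution."""

import pytest

from bnkl import family_query_set, plan_marginals
from bnkl.cached import COMBINATION, MARGINALIZATION, PROTECTED

from .conftest import make_fig_pair, make_random_pair


@pytest.fixture
def fig_queries(fig_pair):
    na, nb = fig_pair
    queries, qmap = family_query_set(na, nb)
    return na, nb, queries, qmap


class TestWorkedExampleTrace:
    """The three-variable star/chain pair, planned query by query.

    Queries: {X1}, {X1,X2}, {X1,X3}, {X2,X3}.  Register ids follow the
    planner clock, which ticks on cache hits too, so the recorded ids are
    1, 2, 4 and 5.
    """

    def test_query_order_and_dedup(self, fig_queries):
        _, _, queries, qmap = fig_queries
        assert [[v.name for v in q] for q in queries] == [
            ["X1"], ["X1", "X2"], ["X1", "X3"], ["X2", "X3"]
        ]
        # shared families map to the same query slot
        assert qmap[("A", "X1")] == qmap[("B", "X1")] == 0
        assert qmap[("A", "X2")] == qmap[("B", "X2")] == 1

    def test_first_query_needs_no_operations(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries[:1])
        assert plan.registers == []
        assert plan.result_ids == [1]  # the root CPT itself, protected
        assert plan.entries[1].time == PROTECTED

    def test_repositories_after_second_query(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries[:2])
        assert len(plan.registers) == 1
        reg = plan.registers[0]
        assert (reg.id, reg.type, reg.arg1, reg.arg2, reg.result) == (
            1, COMBINATION, 1, 2, 4
        )
        times = {pid: plan.entries[pid].time for pid in sorted(plan.entries)}
        assert times == {1: -1, 2: 1, 3: 0, 4: -1}

    def test_combination_for_third_query_has_id_two(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries[:3])
        assert [
            (r.id, r.type, r.arg1, r.arg2, r.result) for r in plan.registers
        ] == [(1, COMBINATION, 1, 2, 4), (2, COMBINATION, 1, 3, 5)]

    def test_full_plan_reuses_first_combination(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries)
        ids = [(r.id, r.type, r.arg1, r.arg2, r.result) for r in plan.registers]
        assert ids == [
            (1, COMBINATION, 1, 2, 4),
            (2, COMBINATION, 1, 3, 5),
            (4, COMBINATION, 4, 3, 6),
            (5, MARGINALIZATION, 6, 0, 7),  # removes X1 (variable index 0)
        ]
        # the hit: fourth query reuses the combination created during query 2
        assert len(plan.hits) == 1
        hit = plan.hits[0]
        assert hit.t == 3
        assert hit.query_index == 4
        assert hit.register.id == 1
        assert hit.register.query_index == 2
        # final marginalization is the only marg register and carries id 5
        margs = [r for r in plan.registers if r.type == MARGINALIZATION]
        assert [r.id for r in margs] == [5]

    def test_final_times_and_protection(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries)
        protected = {pid for pid, e in plan.entries.items() if e.time == PROTECTED}
        assert protected == {1, 4, 5, 7}
        assert plan.entries[3].time == 4  # phi3 last needed by register 4
        assert plan.entries[6].time == 5  # phi6 consumed by the marginalization
        assert plan.entries[2].time == 3  # phi2 last touched by the cache hit

    def test_execution_reclaims_everything_unprotected(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries)
        margs = plan.execute()
        s = plan.stats()
        assert (s.ops, s.rep, s.dels) == (4, 1, 3)  # phi2, phi3, phi6 reclaimed
        for m in margs:
            assert m.total() == pytest.approx(1.0, abs=1e-9)

    def test_dump_mentions_all_registers(self, fig_queries):
        na, _, queries, _ = fig_queries
        plan = plan_marginals(na, queries)
        text = plan.dump()
        for token in ("phi_4", "phi_7", "comb", "marg", "X1"):
            assert token in text
        d = plan.to_dict()
        assert [op["id"] for op in d["operations"]] == [1, 2, 4, 5]


class TestPlanInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_marginals_match_joint_oracle(self, seed):
        na, nb = make_random_pair(seed)
        queries, _ = family_query_set(na, nb.aligned_with(na))
        plan = plan_marginals(na, queries)
        margs = plan.execute()
        joint = na.joint()
        for q, m in zip(plan.queries, margs):
            assert m.allclose(joint.marginalize(q), rtol=1e-9, atol=1e-15)
            assert m.total() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_accounting_identity(self, seed):
        na, nb = make_random_pair(seed)
        queries, _ = family_query_set(na, nb.aligned_with(na))
        plan = plan_marginals(na, queries)
        plan.execute()
        s = plan.stats()
        assert s.cond_calls == s.ops + s.rep
        assert s.executed == s.ops
        if s.rep > 0:
            assert s.executed < s.cond_calls  # cache strictly beats no-cache

    @pytest.mark.parametrize("seed", range(5))
    def test_cache_soundness(self, seed):
        """Recomputing each register from its arguments reproduces its table."""
        na, nb = make_random_pair(seed)
        queries, _ = family_query_set(na, nb.aligned_with(na))
        plan = plan_marginals(na, queries)
        plan.execute()
        tables = {v.index + 1: na.cpts[v] for v in na.variables}
        for reg in plan.registers:
            a = tables[reg.arg1]
            if reg.type == "comb":
                res = a * tables[reg.arg2]
            else:
                res = a.sum_out(na.variables[reg.arg2])
            tables[reg.result] = res
            assert res.variables == plan.entries[reg.result].variables
        for q, pid in zip(plan.queries, plan.result_ids):
            assert tables[pid].allclose(na.joint().marginalize(q), rtol=1e-9, atol=1e-15)

    def test_duplicate_network_plans_with_heavy_reuse(self):
        na, _ = make_random_pair(3)
        queries, _ = family_query_set(na, na)
        plan = plan_marginals(na, queries)
        plan.execute()
        assert len(queries) <= len(na)

    def test_identical_tree_families_share_subplans(self, chain):
        # duplicated family queries must produce at least one repetition
        queries = [chain.family(v) for v in chain.variables]
        plan = plan_marginals(chain, queries + queries[1:])
        plan.execute()
        assert plan.stats().rep > 0

    def test_single_root_query_has_empty_plan(self, chain):
        x1 = chain.variables[0]
        plan = plan_marginals(chain, [(x1,)])
        margs = plan.execute()
        s = plan.stats()
        assert (s.ops, s.rep, s.dels) == (0, 0, 0)
        assert margs[0].allclose(chain.cpts[x1], rtol=1e-12)
        # the returned marginal is a copy, not the live CPT object
        assert margs[0] is not chain.cpts[x1]

    def test_replanning_not_allowed_after_execution(self, chain):
        plan = plan_marginals(chain, [chain.family(v) for v in chain.variables])
        plan.execute()
        with pytest.raises(RuntimeError):
            plan.execute()

    def test_unknown_query_variable_rejected(self, chain):
        from .conftest import make_variables

        stranger = make_variables([2], prefix="Z")[0]
        with pytest.raises(KeyError):
            plan_marginals(chain, [(stranger,)])
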