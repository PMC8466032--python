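"""Potential algebra: projection, multiplication, marginalization, selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bnkl import (
    IncompatiblePotentialError,
    Potential,
    ScopeError,
    Variable,
    canonical_scope,
    iter_configurations,
    project,
)

from .conftest import make_variables, random_potential


def brute_product(a: Potential, b: Potential) -> Potential:
    """Independent nested-loop product over all joint configurations."""
    out_vars = canonical_scope(dict.fromkeys(a.variables + b.variables))
    table = np.empty(tuple(v.cardinality for v in out_vars))
    for cfg in iter_configurations(out_vars):
        idx = tuple(cfg[v] for v in out_vars)
        table[idx] = a(project(cfg, a.variables)) * b(project(cfg, b.variables))
    return Potential(out_vars, table)


@st.composite
def potential_pair(draw):
    cards = draw(st.lists(st.integers(2, 3), min_size=2, max_size=4))
    vs = make_variables(cards)
    na = draw(st.integers(1, len(vs)))
    nb = draw(st.integers(1, len(vs)))
    seed = draw(st.integers(0, 2**16))
    rng = np.random.default_rng(seed)
    a_vars = tuple(rng.choice(vs, size=na, replace=False))
    b_vars = tuple(rng.choice(vs, size=nb, replace=False))
    return random_potential(rng, a_vars), random_potential(rng, b_vars)


class TestProject:
    def test_drops_out_of_scope_values(self):
        x1, x2 = make_variables([2, 2])
        cfg = {x2: 0, x1: 0}
        assert project(cfg, (x2,)) == {x2: 0}

    def test_full_scope_is_identity_and_empty_scope_is_empty(self):
        x1, x2 = make_variables([2, 3])
        cfg = {x1: 1, x2: 2}
        assert project(cfg, (x1, x2)) == cfg
        assert project(cfg, ()) == {}

    def test_missing_variable_raises(self):
        x1, x2 = make_variables([2, 2])
        with pytest.raises(ScopeError):
            project({x1: 0}, (x2,))


class TestMultiply:
    def test_scope_is_union(self):
        x1, x2, x3 = make_variables([2, 2, 2])
        rng = np.random.default_rng(0)
        phi2 = random_potential(rng, (x2, x1))
        phi3 = random_potential(rng, (x3, x2))
        assert (phi2 * phi3).variables == (x1, x2, x3)

    def test_unit_is_identity(self):
        rng = np.random.default_rng(1)
        phi = random_potential(rng, tuple(make_variables([2, 3])))
        assert (phi * Potential.unit()).equals(phi)
        assert (Potential.unit() * phi).equals(phi)

    @given(potential_pair())
    def test_matches_nested_loop_product(self, pair):
        a, b = pair
        assert (a * b).allclose(brute_product(a, b), rtol=1e-12)

    @given(potential_pair())
    def test_commutative_and_associative(self, pair):
        a, b = pair
        assert (a * b).allclose(b * a, rtol=1e-12)
        c = Potential(a.variables, a.table + 0.5)
        assert ((a * b) * c).allclose(a * (b * c), rtol=1e-12)

    def test_mismatched_shared_cardinality_raises(self):
        xa = Variable("X1", ("a", "b"), 0)
        xb = Variable("X1", ("a", "b", "c"), 0)
        pa = Potential((xa,), [1.0, 2.0])
        pb = Potential((xb,), [1.0, 2.0, 3.0])
        with pytest.raises(IncompatiblePotentialError):
            pa * pb


class TestSumOut:
    def test_cpt_sums_to_ones(self, chain):
        x2, x3 = chain.variables[1], chain.variables[2]
        res = chain.cpts[x3].sum_out(x3)
        assert res.variables == (x2,)
        assert np.allclose(res.table, 1.0)

    def test_cardinality_one_variable_drops_silently(self):
        x1 = Variable("X1", ("only",), 0)
        x2 = Variable("X2", ("a", "b"), 1)
        phi = Potential((x1, x2), [[0.4, 0.6]])
        res = phi.sum_out(x1)
        assert res.variables == (x2,)
        assert np.allclose(res.table, [0.4, 0.6])

    @given(st.integers(0, 2**16))
    def test_conserves_total_mass(self, seed):
        rng = np.random.default_rng(seed)
        vs = tuple(make_variables([2, 3, 2]))
        phi = random_potential(rng, vs)
        for v in vs:
            assert phi.sum_out(v).total() == pytest.approx(phi.total(), rel=1e-12)

    def test_absent_variable_raises(self):
        x1, x2 = make_variables([2, 2])
        phi = Potential((x1,), [1.0, 2.0])
        with pytest.raises(ScopeError):
            phi.sum_out(x2)


class TestMarginalize:
    def test_identity_and_empty_scope(self):
        rng = np.random.default_rng(2)
        vs = tuple(make_variables([2, 2]))
        phi = random_potential(rng, vs)
        assert phi.marginalize(vs).equals(phi)
        empty = phi.marginalize(())
        assert empty.variables == ()
        assert float(empty.table) == pytest.approx(phi.total(), rel=1e-12)

    @given(st.integers(0, 2**16))
    def test_removal_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        vs = tuple(make_variables([2, 3, 2, 2]))
        phi = random_potential(rng, vs)
        keep = vs[1:2]
        drop = [v for v in vs if v not in keep]
        a = phi
        for v in drop:
            a = a.sum_out(v)
        b = phi
        for v in reversed(drop):
            b = b.sum_out(v)
        assert a.allclose(b, rtol=1e-12)
        assert a.allclose(phi.marginalize(keep), rtol=1e-12)

    def test_non_subset_raises(self):
        x1, x2 = make_variables([2, 2])
        phi = Potential((x1,), [1.0, 2.0])
        with pytest.raises(ScopeError):
            phi.marginalize((x2,))


class TestRestrict:
    def test_slices_on_overlap_only(self, chain):
        # restricting P(X3|X2) at (X1=0, X2=1) keeps the X2=1 column
        x1, x2, x3 = chain.variables
        phi3 = chain.cpts[x3]
        res = phi3.restrict({x1: 0, x2: 1})
        assert res.variables == (x3,)
        assert np.allclose(res.table, phi3.table[1, :])  # canonical axes (X2, X3)

    def test_disjoint_configuration_is_identity(self):
        x1, x2, x3 = make_variables([2, 2, 2])
        phi = Potential((x1,), [0.5, 0.5])
        assert phi.restrict({x2: 1, x3: 0}) is phi

    def test_out_of_range_state_raises(self):
        (x1,) = make_variables([2])
        phi = Potential((x1,), [0.5, 0.5])
        with pytest.raises(ValueError):
            phi.restrict({x1: 5})

    @given(st.integers(0, 2**16))
    def test_restrict_then_sum_equals_slice_sum(self, seed):
        rng = np.random.default_rng(seed)
        vs = tuple(make_variables([2, 3, 2]))
        phi = random_potential(rng, vs)
        z = {vs[0]: 1}
        expected = sum(
            phi({**cfg, **z}) for cfg in iter_configurations(vs[1:])
        )
        assert phi.restrict(z).total() == pytest.approx(expected, rel=1e-12)

    @given(potential_pair())
    def test_distributes_over_multiplication(self, pair):
        a, b = pair
        shared = a.variables[0]
        z = {shared: shared.cardinality - 1}
        lhs = (a * b).restrict(z)
        rhs = a.restrict(z) * b.restrict(z)
        assert lhs.allclose(rhs, rtol=1e-12)


class TestScalars:
    def test_empty_scope_potential_is_first_class(self):
        s = Potential((), 2.5)
        assert s.variables == ()
        assert s.total() == 2.5
        (x1,) = make_variables([2])
        phi = Potential((x1,), [0.1, 0.9])
        assert (s * phi).allclose(Potential((x1,), [0.25, 2.25]), rtol=1e-12)

    def test_canonical_order_is_applied_on_construction(self):
        x1, x2 = make_variables([2, 3])
        arr = np.arange(6.0).reshape(3, 2)  # given as (X2, X1)
        phi = Potential((x2, x1), arr)
        assert phi.variables == (x1, x2)
        assert np.array_equal(phi.table, arr.T)

    def test_negative_values_rejected(self):
        (x1,) = make_variables([2])
        with pytest.raises(ValueError):
            Potential((x1,), [0.5, -0.1])
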