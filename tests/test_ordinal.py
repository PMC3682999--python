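"""Ordinal machinery: connection matrices, maximal chains, invariants.

The London worked example (combined-WordNet similarities vs decoding
conditional probabilities on the first 10-word geography set) provides
frozen expected structures; brute-force oracles cover random small orders.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordsim import (
    ValidationError,
    WordSet,
    build_connection_matrix,
    build_order_family,
    intersect_orders,
    join_invariants,
    maximal_chains,
    maximal_common_subsequences,
    orders_identical,
)

# Connection matrix for the focus word London derived from the
# combined-WordNet similarity column, word order
# (London, Moscow, Paris, north, south, east, west, Germany, Poland, Russia).
LONDON_LANGUAGE_CONN = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 0, 1, 0, 0, 0, 0, 0, 0, 0],
        [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0, 1, 1, 1],
        [1, 1, 1, 1, 0, 0, 0, 1, 1, 1],
        [1, 1, 1, 1, 1, 0, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 0, 0, 1, 1, 1],
        [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0, 1, 0, 1],
        [1, 1, 1, 0, 0, 0, 0, 1, 0, 0],
    ]
)

LANGUAGE_CHAIN = (
    "London Paris Moscow Germany Russia Poland north south west east".split()
)
BRAIN_CHAINS = [
    "London Paris Moscow Germany north Russia Poland east south".split(),
    "London Paris Moscow Germany north Russia Poland east west".split(),
]
INVARIANT_CHAINS = [
    "London Paris Moscow Germany Russia Poland south".split(),
    "London Paris Moscow Germany Russia Poland east".split(),
    "London Paris Moscow Germany Russia Poland west".split(),
]


def random_order(n, rng, tie_decimals=1):
    words = WordSet([f"w{i}" for i in range(n)])
    values = rng.uniform(0, 1, size=n).round(tie_decimals)
    return build_connection_matrix(values, 0, words, None), values, words


class TestBuildConnectionMatrix:
    def test_london_language_column_reproduces_printed_matrix(self, fx):
        order = build_connection_matrix(fx.london_language, 0, fx.words)
        np.testing.assert_array_equal(order.conn, LONDON_LANGUAGE_CONN)

    def test_all_equal_row_gives_empty_order(self):
        words = WordSet(list("abc"))
        order = build_connection_matrix([2.0, 2.0, 2.0], 0, words)
        assert order.n_edges == 0

    def test_three_value_example(self):
        words = WordSet(list("abc"))
        order = build_connection_matrix([3, 1, 2], 0, words)
        np.testing.assert_array_equal(
            order.conn, [[0, 0, 0], [1, 0, 1], [1, 0, 0]]
        )

    def test_tie_decimals_rounds_before_comparing(self):
        words = WordSet(list("ab"))
        tied = build_connection_matrix([0.1231, 0.1234], 0, words, tie_decimals=3)
        assert tied.n_edges == 0
        untied = build_connection_matrix([0.1231, 0.1234], 0, words)
        assert untied.n_edges == 1

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            build_connection_matrix([1.0, np.nan], 0, WordSet(list("ab")))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_order_axioms_and_edge_count_law(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        order, values, _ = random_order(n, rng)
        conn = order.conn
        assert np.diagonal(conn).sum() == 0
        assert not (conn & conn.T).any()
        closure = (conn @ conn > 0)
        assert not (closure & (conn == 0)).any()
        _, group_sizes = np.unique(values, return_counts=True)
        expected_edges = n * (n - 1) // 2 - sum(
            g * (g - 1) // 2 for g in group_sizes
        )
        assert order.n_edges == expected_edges


class TestOrdersIdentical:
    def test_reflexive(self, fx):
        a = build_connection_matrix(fx.london_language, 0, fx.words)
        assert orders_identical(a, a)

    def test_language_vs_brain_orders_differ(self, fx):
        a = build_connection_matrix(fx.london_language, 0, fx.words)
        b = build_connection_matrix(fx.london_brain, 0, fx.words)
        assert not orders_identical(a, b)

    def test_single_flipped_edge_detected(self):
        rng = np.random.default_rng(3)
        order, _, words = random_order(6, rng, tie_decimals=3)
        conn = order.conn.copy()
        i, j = np.argwhere(conn)[0]
        conn[i, j] = 0
        conn[j, i] = 1
        from ordsim.ordinal import StrictPartialOrder

        try:
            other = StrictPartialOrder(words, 0, conn)
        except ValidationError:
            return  # flip broke transitivity; difference is self-evident
        assert not orders_identical(order, other)


class TestIntersectOrders:
    def test_idempotent_and_absorbing(self, fx):
        a = build_connection_matrix(fx.london_language, 0, fx.words)
        empty = build_connection_matrix([1.0] * 10, 0, fx.words)
        assert orders_identical(intersect_orders(a, a), a)
        assert intersect_orders(a, empty).n_edges == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        words = WordSet([f"w{i}" for i in range(6)])
        va = rng.uniform(0, 1, 6).round(1)
        vb = rng.uniform(0, 1, 6).round(1)
        a = build_connection_matrix(va, 0, words)
        b = build_connection_matrix(vb, 0, words)
        inter = intersect_orders(a, b)
        for i in range(6):
            for j in range(6):
                expected = int(va[j] > va[i] and vb[j] > vb[i])
                assert inter.conn[i, j] == expected


class TestMaximalChains:
    def test_brain_column_yields_two_nine_word_chains(self, fx):
        order = build_connection_matrix(fx.london_brain, 0, fx.words)
        chains = maximal_chains(order)
        assert sorted(map(list, chains.chains)) == sorted(BRAIN_CHAINS)

    def test_language_column_yields_one_ten_word_chain(self, fx):
        order = build_connection_matrix(fx.london_language, 0, fx.words)
        chains = maximal_chains(order)
        assert [list(c) for c in chains.chains] == [LANGUAGE_CHAIN]

    def test_total_antichain_gives_singletons(self):
        words = WordSet(list("abc"))
        order = build_connection_matrix([1.0, 1.0, 1.0], 0, words)
        assert maximal_chains(order).chains == (("a",), ("b",), ("c",))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_chain_count_and_length_laws(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        order, values, _ = random_order(n, rng)
        chains = maximal_chains(order).chains
        _, group_sizes = np.unique(values, return_counts=True)
        assert len(chains) == int(np.prod(group_sizes))
        expected_len = n - sum(g - 1 for g in group_sizes)
        assert all(len(c) == expected_len for c in chains)
        # every consecutive pair is strictly ordered by the source values
        val = {f"w{i}": v for i, v in enumerate(values)}
        for c in chains:
            assert all(val[c[k]] > val[c[k + 1]] for k in range(len(c) - 1))


def brute_force_common_subsequences(chains_a, chains_b):
    """All common subsequences by exhaustive subset enumeration."""
    common = set()
    for ca in chains_a:
        for r in range(1, len(ca) + 1):
            for sub in itertools.combinations(ca, r):
                for cb in chains_b:
                    it = iter(cb)
                    if all(x in it for x in sub):
                        common.add(sub)
                        break
    if not common:
        return 0, set()
    best = max(map(len, common))
    return best, {c for c in common if len(c) == best}


class TestMaximalCommonSubsequences:
    def test_london_invariant_is_three_seven_word_chains(self, fx):
        ob = build_connection_matrix(fx.london_brain, 0, fx.words)
        op = build_connection_matrix(fx.london_language, 0, fx.words)
        inv = maximal_common_subsequences(
            maximal_chains(ob), maximal_chains(op), ob, op
        )
        assert inv.max_length == 7
        assert sorted(map(list, inv.invariant_chains)) == sorted(INVARIANT_CHAINS)

    def test_identical_singleton_chain_sets(self):
        words = WordSet(list("abc"))
        order = build_connection_matrix([3, 2, 1], 0, words)
        chains = maximal_chains(order)
        inv = maximal_common_subsequences(chains, chains, order, order)
        assert inv.max_length == 3
        assert inv.invariant_chains == (("a", "b", "c"),)

    def test_reversed_chains_share_only_singletons(self):
        words = WordSet(list("abc"))
        fwd = build_connection_matrix([3, 2, 1], 0, words)
        rev = build_connection_matrix([1, 2, 3], 0, words)
        inv = maximal_common_subsequences(
            maximal_chains(fwd), maximal_chains(rev), fwd, rev
        )
        assert inv.max_length == 1
        assert set(inv.invariant_chains) == {("a",), ("b",), ("c",)}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        words = WordSet([f"w{i}" for i in range(6)])
        va = rng.uniform(0, 1, 6).round(1)
        vb = rng.uniform(0, 1, 6).round(1)
        a = build_connection_matrix(va, 0, words)
        b = build_connection_matrix(vb, 0, words)
        ca, cb = maximal_chains(a), maximal_chains(b)
        inv = maximal_common_subsequences(ca, cb, a, b)
        best_len, best = brute_force_common_subsequences(ca.chains, cb.chains)
        assert inv.max_length == best_len
        assert set(inv.invariant_chains) == best
        assert inv.max_length <= min(
            min(map(len, ca.chains)), min(map(len, cb.chains))
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_chains_are_common_subsequences(self, seed):
        def is_subseq(sub, seq):
            it = iter(seq)
            return all(x in it for x in sub)

        rng = np.random.default_rng(100 + seed)
        words = WordSet([f"w{i}" for i in range(7)])
        a = build_connection_matrix(rng.uniform(0, 1, 7).round(1), 0, words)
        b = build_connection_matrix(rng.uniform(0, 1, 7).round(1), 0, words)
        ca, cb = maximal_chains(a), maximal_chains(b)
        inv = maximal_common_subsequences(ca, cb, a, b)
        for chain in inv.invariant_chains:
            assert any(is_subseq(chain, c) for c in ca.chains)
            assert any(is_subseq(chain, c) for c in cb.chains)


class TestJoinInvariants:
    def test_single_chain_joins_to_its_path(self):
        words = WordSet(list("abc"))
        order = build_connection_matrix([3, 2, 1], 0, words)
        chains = maximal_chains(order)
        inv = maximal_common_subsequences(chains, chains, order, order)
        assert join_invariants(inv) == [("a", "b"), ("b", "c")]

    def test_london_join_is_shared_path_with_three_branches(self, fx):
        ob = build_connection_matrix(fx.london_brain, 0, fx.words)
        op = build_connection_matrix(fx.london_language, 0, fx.words)
        inv = maximal_common_subsequences(
            maximal_chains(ob), maximal_chains(op), ob, op
        )
        edges = set(join_invariants(inv))
        path = {
            ("London", "Paris"),
            ("Paris", "Moscow"),
            ("Moscow", "Germany"),
            ("Germany", "Russia"),
            ("Russia", "Poland"),
        }
        branches = {("Poland", "south"), ("Poland", "west"), ("Poland", "east")}
        assert edges == path | branches

    @pytest.mark.parametrize("seed", range(4))
    def test_join_is_acyclic(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        words = WordSet([f"w{i}" for i in range(7)])
        a = build_connection_matrix(rng.uniform(0, 1, 7).round(1), 0, words)
        b = build_connection_matrix(rng.uniform(0, 1, 7).round(1), 0, words)
        inv = maximal_common_subsequences(
            maximal_chains(a), maximal_chains(b), a, b
        )
        g = nx.DiGraph(join_invariants(inv))
        assert nx.is_directed_acyclic_graph(g)


def test_order_family_builds_one_order_per_word(fx):
    mat = np.tile(fx.london_language, (10, 1))
    fam = build_order_family(mat, fx.words)
    assert len(fam.orders) == 10
    assert all(o.focus == i for i, o in enumerate(fam.orders))
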