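"""Strict partial orders of similarity differences and their invariants.

For a focus word w and a row of similarity values (conditional probabilities
p_wj for decoding data, or semantic similarities s_wj), the ordinal relation
of similarity differences ranks every word by how similar it is to w.  It is
encoded as a binary connection matrix C with C[i, j] = 1 iff word j is
strictly more similar to w than word i (j's similarity difference with w is
smaller).  Ties leave both directions 0, so the relation is a strict partial
order: irreflexive, asymmetric and transitive.

Comparing a brain-derived order with a semantic-model-derived order for the
same focus word proceeds through maximal chains (one representative per tie
group, most similar first), all maximal-length common subsequences between
the two chain sets, and the element-wise intersection of the two orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import networkx as nx
import numpy as np

from .core import ValidationError, WordSet

__all__ = [
    "StrictPartialOrder",
    "OrderFamily",
    "ChainSet",
    "InvariantResult",
    "build_connection_matrix",
    "build_order_family",
    "orders_identical",
    "intersect_orders",
    "maximal_chains",
    "maximal_common_subsequences",
    "join_invariants",
]


def _check_strict_order(conn: np.ndarray) -> None:
    if np.diagonal(conn).any():
        raise ValidationError("connection matrix has a reflexive edge")
    if (conn & conn.T).any():
        raise ValidationError("connection matrix has a symmetric edge pair")
    closure = (conn @ conn > 0).astype(np.int8)
    if ((closure == 1) & (conn == 0)).any():
        raise ValidationError("connection matrix is not transitive")


@dataclass(frozen=True)
class StrictPartialOrder:
    """Ordinal relation of similarity differences for one focus word.

    ``conn[i, j] == 1`` iff word j is strictly more similar to the focus
    word than word i.
    """

    words: WordSet
    focus: int
    conn: np.ndarray

    def __post_init__(self):
        n = len(self.words)
        conn = np.asarray(self.conn)
        if conn.shape != (n, n):
            raise ValidationError(f"connection matrix must be {n}x{n}")
        if not np.isin(conn, (0, 1)).all():
            raise ValidationError("connection matrix must be binary")
        conn = conn.astype(np.int8)
        _check_strict_order(conn)
        if not 0 <= self.focus < n:
            raise ValidationError("focus index out of range")
        object.__setattr__(self, "conn", conn)

    @property
    def focus_word(self) -> str:
        return self.words.labels[self.focus]

    @property
    def n_edges(self) -> int:
        return int(self.conn.sum())

    def _require_comparable(self, other: "StrictPartialOrder") -> None:
        if self.words.labels != other.words.labels:
            raise ValidationError("orders are over different word sets")
        if self.focus != other.focus:
            raise ValidationError(
                f"orders have different focus words "
                f"({self.focus_word!r} vs {other.focus_word!r})"
            )


@dataclass(frozen=True)
class OrderFamily:
    """One strict partial order per focus word, plus the value matrix the
    orders were derived from (one row per focus word)."""

    words: WordSet
    orders: tuple[StrictPartialOrder, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.orders) != len(self.words):
            raise ValidationError("need exactly one order per word")
        for i, o in enumerate(self.orders):
            if o.focus != i:
                raise ValidationError("orders[i] must have focus i")
        object.__setattr__(self, "values", np.asarray(self.values, float))


@dataclass(frozen=True)
class ChainSet:
    """All maximal chains of one order, focus word first.

    A maximal chain is a totally ordered subset extendable by no word; every
    tie group contributes exactly one representative per chain, so the chain
    count is the product of tie-group sizes.
    """

    focus: int
    chains: tuple[tuple[str, ...], ...]


@dataclass(frozen=True)
class InvariantResult:
    """Common ordinal structure of two orders for the same focus word."""

    focus: int
    invariant_chains: tuple[tuple[str, ...], ...]
    max_length: int
    intersected_order: StrictPartialOrder


def build_connection_matrix(
    values: Sequence[float],
    focus: int,
    words: WordSet,
    tie_decimals: int | None = None,
) -> StrictPartialOrder:
    """Build the strict order for one focus word from its row of values.

    Ties (exact equality, optionally after rounding to ``tie_decimals``)
    leave both directions 0.  The focus word participates in its own
    ordering; with a sensible similarity row it has the largest value and
    heads every maximal chain.
    """
    vals = np.asarray(values, float)
    if vals.shape != (len(words),):
        raise ValidationError(f"expected {len(words)} values, got {vals.shape}")
    if not np.isfinite(vals).all():
        raise ValidationError("values must be finite")
    if tie_decimals is not None:
        vals = np.round(vals, tie_decimals)
    conn = (vals[None, :] > vals[:, None]).astype(np.int8)
    return StrictPartialOrder(words, focus, conn)


def build_order_family(
    value_matrix: np.ndarray, words: WordSet, tie_decimals: int | None = None
) -> OrderFamily:
    """One order per word, from row i of a probability or similarity matrix."""
    values = np.asarray(value_matrix, float)
    orders = tuple(
        build_connection_matrix(values[i], i, words, tie_decimals)
        for i in range(len(words))
    )
    return OrderFamily(words, orders, values)


def orders_identical(a: StrictPartialOrder, b: StrictPartialOrder) -> bool:
    """Element-by-element equality of the connection matrices — the
    label-preserving order-isomorphism check."""
    a._require_comparable(b)
    return bool(np.array_equal(a.conn, b.conn))


def intersect_orders(a: StrictPartialOrder, b: StrictPartialOrder) -> StrictPartialOrder:
    """Element-wise AND of the two connection matrices.

    The intersection of two strict partial orders is again a strict partial
    order; the constructor re-asserts irreflexivity, asymmetry and
    transitivity anyway.
    """
    a._require_comparable(b)
    return StrictPartialOrder(a.words, a.focus, a.conn & b.conn)


def maximal_chains(order: StrictPartialOrder) -> ChainSet:
    """Enumerate all maximal chains, most-similar word first.

    The precedence DAG has an edge j -> i whenever ``conn[i, j] == 1`` (j is
    strictly more similar to the focus than i).  Maximal chains are exactly
    the paths from a minimal to a maximal node of the Hasse diagram
    (transitive reduction).  Chains are returned in lexicographic order of
    word indices for determinism.
    """
    n = len(order.words)
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    rows, cols = np.nonzero(order.conn)
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))  # j -> i
    hasse = nx.transitive_reduction(g)
    sources = sorted(v for v in hasse if hasse.in_degree(v) == 0)
    sinks = {v for v in hasse if hasse.out_degree(v) == 0}

    chains: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        node = path[-1]
        if node in sinks:
            chains.append(tuple(path))
            return
        for nxt in sorted(hasse.successors(node)):
            path.append(nxt)
            extend(path)
            path.pop()

    for s in sources:
        extend([s])
    chains.sort()
    labels = order.words.labels
    return ChainSet(order.focus, tuple(tuple(labels[i] for i in c) for c in chains))


def _all_lcs(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[int, frozenset]:
    """Length of the longest common subsequence of two sequences together
    with the set of all distinct LCSs."""
    la, lb = len(a), len(b)
    # length DP
    L = np.zeros((la + 1, lb + 1), dtype=int)
    for i in range(la - 1, -1, -1):
        for j in range(lb - 1, -1, -1):
            if a[i] == b[j]:
                L[i, j] = 1 + L[i + 1, j + 1]
            else:
                L[i, j] = max(L[i + 1, j], L[i, j + 1])

    @lru_cache(maxsize=None)
    def collect(i: int, j: int) -> frozenset:
        if L[i, j] == 0:
            return frozenset({()})
        out = set()
        if a[i] == b[j]:
            for tail in collect(i + 1, j + 1):
                out.add((a[i],) + tail)
        else:
            if L[i + 1, j] == L[i, j]:
                out |= collect(i + 1, j)
            if L[i, j + 1] == L[i, j]:
                out |= collect(i, j + 1)
        return frozenset(out)

    result = collect(0, 0)
    collect.cache_clear()
    return int(L[0, 0]), result


def maximal_common_subsequences(
    a: ChainSet, b: ChainSet, order_a: StrictPartialOrder, order_b: StrictPartialOrder
) -> InvariantResult:
    """All maximal-length common subsequences across the two chain sets.

    Over every pair (chain of a, chain of b) the longest common subsequence
    is computed; the invariant chains are all distinct common subsequences
    attaining the maximal length over all pairs, deduplicated and ordered
    lexicographically by word index.
    """
    if a.focus != b.focus:
        raise ValidationError("chain sets have different focus words")
    if not a.chains or not b.chains:
        raise ValidationError("empty chain set")
    best_len = 0
    best: set[tuple[str, ...]] = set()
    for ca in a.chains:
        for cb in b.chains:
            length, seqs = _all_lcs(ca, cb)
            if length > best_len:
                best_len, best = length, set(seqs)
            elif length == best_len:
                best |= seqs
    idx = {w: i for i, w in enumerate(order_a.words.labels)}
    ordered = tuple(
        sorted(best, key=lambda seq: tuple(idx[w] for w in seq))
    )
    return InvariantResult(
        focus=a.focus,
        invariant_chains=ordered,
        max_length=best_len,
        intersected_order=intersect_orders(order_a, order_b),
    )


def join_invariants(inv: InvariantResult) -> list[tuple[str, str]]:
    """Join the invariant chains into one DAG edge list.

    Consecutive-pair edges of all invariant chains are unioned and
    transitively reduced; the result is the joint invariant order drawn as a
    directed acyclic graph.
    """
    if not inv.invariant_chains:
        raise ValidationError("no invariant chains to join")
    g = nx.DiGraph()
    for chain in inv.invariant_chains:
        g.add_nodes_from(chain)
        g.add_edges_from(zip(chain, chain[1:]))
    if not nx.is_directed_acyclic_graph(g):  # impossible for real chains
        raise AssertionError("joined invariant chains formed a cycle")
    reduced = nx.transitive_reduction(g)
    idx = {w: i for i, w in enumerate(inv.intersected_order.words.labels)}
    return sorted(reduced.edges(), key=lambda e: (idx[e[0]], idx[e[1]]))


def to_dot(edges: list[tuple[str, str]]) -> str:
    """Render an edge list as a minimal DOT digraph."""
    lines = ["digraph invariant {"]
    for u, v in edges:
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
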