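"""Graph filtration primitives for weighted complete networks.

A weighted complete network on ``p`` nodes is stored as the length
``q = p(p-1)/2`` vector of its edge weights in a canonical upper-triangle
order.  Thresholding the network at increasing filtration values deletes
edges from the lowest weight to the highest; tracking connected components
and independent cycles along the way yields the birth-death decomposition:
the ``p - 1`` weights of the maximum spanning tree are the birth values of
connected components and the remaining ``(p-1)(p-2)/2`` weights are the
death values of cycles.  Together they partition the weight vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "WeightedNetwork",
    "Barcode",
    "BettiCurve",
    "EulerReport",
    "TieWarning",
    "edge_pairs",
    "edge_index",
    "birth_death_decomposition",
    "betti_curves",
    "euler_check",
]


class TieWarning(UserWarning):
    """Emitted when tied edge weights force a deterministic tie-break."""


def edge_pairs(p: int) -> tuple[NDArray[np.intp], NDArray[np.intp]]:
    """Return the (i, j) node pairs of the canonical edge ordering.

    The ordering is row-major over the strict upper triangle: (0,1), (0,2),
    ..., (0,p-1), (1,2), ..., (p-2,p-1), with 0-based node indices.
    """
    iu = np.triu_indices(p, k=1)
    return iu[0], iu[1]


def edge_index(i: int, j: int, p: int) -> int:
    """Canonical index of edge (i, j), i != j, in the weight vector."""
    if i == j:
        raise ValueError("self-loops have no canonical edge index")
    if not (0 <= i < p and 0 <= j < p):
        raise ValueError(f"node indices ({i}, {j}) out of range for p={p}")
    if i > j:
        i, j = j, i
    return i * p - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class WeightedNetwork:
    """Complete graph with ``p`` nodes and canonical edge-weight vector.

    Parameters
    ----------
    p
        Number of nodes, at least 2.
    weights
        Length ``p(p-1)/2`` vector of finite real edge weights, in the
        canonical row-major upper-triangle order (see :func:`edge_pairs`).
    """

    p: int
    weights: NDArray[np.float64]

    def __post_init__(self) -> None:
        if int(self.p) != self.p or self.p < 2:
            raise ValueError(f"node count p must be an integer >= 2, got {self.p}")
        w = np.asarray(self.weights, dtype=float)
        q = self.p * (self.p - 1) // 2
        if w.ndim != 1 or w.shape[0] != q:
            raise ValueError(
                f"expected {q} = p(p-1)/2 weights for p={self.p}, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("edge weights must be finite")
        object.__setattr__(self, "p", int(self.p))
        object.__setattr__(self, "weights", w)

    @property
    def q(self) -> int:
        """Number of edges, p(p-1)/2."""
        return self.p * (self.p - 1) // 2

    def adjacency(self) -> NDArray[np.float64]:
        """Dense symmetric adjacency matrix with zero diagonal."""
        A = np.zeros((self.p, self.p))
        i, j = edge_pairs(self.p)
        A[i, j] = self.weights
        A[j, i] = self.weights
        return A

    @classmethod
    def from_adjacency(cls, A: ArrayLike) -> "WeightedNetwork":
        """Build a network from a symmetric matrix, ignoring the diagonal."""
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got shape {A.shape}")
        i, j = edge_pairs(A.shape[0])
        return cls(A.shape[0], A[i, j])


@dataclass(frozen=True)
class Barcode:
    """Birth values of connected components and death values of cycles.

    ``births`` are the sorted weights of the maximum spanning tree
    (length ``m0 = p - 1``); ``deaths`` are the sorted remaining weights
    (length ``m1 = (p-1)(p-2)/2``).  ``birth_ranks`` / ``death_ranks`` give
    the 1-based position of each value among all ``q`` sorted edge weights.
    """

    births: NDArray[np.float64]
    deaths: NDArray[np.float64]
    birth_ranks: NDArray[np.intp]
    death_ranks: NDArray[np.intp]

    def __post_init__(self) -> None:
        b = np.asarray(self.births, dtype=float)
        d = np.asarray(self.deaths, dtype=float)
        br = np.asarray(self.birth_ranks, dtype=np.intp)
        dr = np.asarray(self.death_ranks, dtype=np.intp)
        if b.shape != br.shape or d.shape != dr.shape:
            raise ValueError("values and ranks must have matching shapes")
        q = b.size + d.size
        ranks = np.concatenate([br, dr])
        if not np.array_equal(np.sort(ranks), np.arange(1, q + 1)):
            raise ValueError("birth and death ranks must partition {1, ..., q}")
        object.__setattr__(self, "births", b)
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "birth_ranks", br)
        object.__setattr__(self, "death_ranks", dr)

    @property
    def m0(self) -> int:
        return self.births.size

    @property
    def m1(self) -> int:
        return self.deaths.size

    @property
    def q(self) -> int:
        return self.m0 + self.m1

    @property
    def p(self) -> int:
        """Node count recovered from m0 = p - 1."""
        return self.m0 + 1


@dataclass(frozen=True)
class BettiCurve:
    """Right-continuous integer step function over filtration values.

    ``levels`` has one more entry than ``knots``: ``levels[0]`` is the value
    below the first knot and ``levels[k+1]`` is the value on
    ``[knots[k], knots[k+1])``.  Jumps occur AT the knot (an edge with weight
    exactly equal to the threshold is already absent, matching the strict
    ``w > eps`` rule).
    """

    knots: NDArray[np.float64]
    levels: NDArray[np.intp]
    dimension: int

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        levels = np.asarray(self.levels, dtype=np.intp)
        if levels.size != knots.size + 1:
            raise ValueError("levels must have exactly one more entry than knots")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.dimension not in (0, 1):
            raise ValueError("dimension must be 0 or 1")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "levels", levels)

    def __call__(self, eps: ArrayLike) -> NDArray[np.intp]:
        """Evaluate the Betti number at filtration value(s) ``eps``."""
        idx = np.searchsorted(self.knots, np.asarray(eps, dtype=float), side="right")
        return self.levels[idx]


def _sort_order(weights: NDArray[np.float64], descending: bool) -> NDArray[np.intp]:
    # stable sort keyed on weight; canonical edge index breaks ties
    idx = np.arange(weights.size)
    key = -weights if descending else weights
    return np.lexsort((idx, key))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def birth_death_decomposition(net: WeightedNetwork) -> Barcode:
    """Partition the edge weights into component births and cycle deaths.

    Births are the weights of the maximum spanning tree, found by Kruskal's
    algorithm on weights sorted descending; all remaining weights are deaths.
    Tied weights are resolved by canonical edge index (deterministic) and a
    :class:`TieWarning` is emitted, since the underlying model assumes
    continuous weights where ties have probability zero.
    """
    w = net.weights
    q = net.q
    if np.unique(w).size < q:
        warnings.warn(
            "tied edge weights detected; ties broken by canonical edge index",
            TieWarning,
            stacklevel=2,
        )
    src, dst = edge_pairs(net.p)

    uf = _UnionFind(net.p)
    is_birth = np.zeros(q, dtype=bool)
    for e in _sort_order(w, descending=True):
        if uf.union(int(src[e]), int(dst[e])):
            is_birth[e] = True

    asc = _sort_order(w, descending=False)
    rank = np.empty(q, dtype=np.intp)
    rank[asc] = np.arange(1, q + 1)

    birth_ranks = np.sort(rank[is_birth])
    death_ranks = np.sort(rank[~is_birth])
    w_sorted = w[asc]
    return Barcode(
        births=w_sorted[birth_ranks - 1],
        deaths=w_sorted[death_ranks - 1],
        birth_ranks=birth_ranks,
        death_ranks=death_ranks,
    )


def betti_curves(bar: Barcode, p: int | None = None) -> tuple[BettiCurve, BettiCurve]:
    """Betti-0 and Betti-1 curves of a barcode.

    beta0(eps) = 1 + #{births <= eps} climbs from 1 (complete graph, all
    edges present) to p; beta1(eps) = m1 - #{deaths <= eps} falls from m1
    to 0.  Both are right-continuous.
    """
    if p is not None and p != bar.p:
        raise ValueError(f"barcode has m0={bar.m0}, inconsistent with p={p}")

    bknots, bcounts = np.unique(bar.births, return_counts=True)
    b0 = BettiCurve(
        knots=bknots,
        levels=np.concatenate([[1], 1 + np.cumsum(bcounts)]),
        dimension=0,
    )
    dknots, dcounts = np.unique(bar.deaths, return_counts=True)
    b1 = BettiCurve(
        knots=dknots,
        levels=np.concatenate([[bar.m1], bar.m1 - np.cumsum(dcounts)]),
        dimension=1,
    )
    return b0, b1


@dataclass(frozen=True)
class EulerReport:
    """Outcome of the Euler-characteristic self check."""

    ok: bool
    n_checked: int
    failures: list[float] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def euler_check(net: WeightedNetwork, bar: Barcode) -> EulerReport:
    """Verify beta0 - beta1 = p - #{w > eps} at every threshold.

    Evaluated at each distinct edge weight and at +/- infinity.  Holds by
    construction for any valid decomposition; failing indicates a corrupted
    barcode.
    """
    b0, b1 = betti_curves(bar)
    thresholds = np.concatenate([[-np.inf], np.unique(net.weights), [np.inf]])
    failures: list[float] = []
    for eps in thresholds:
        chi = int(b0(eps)) - int(b1(eps))
        n_edges = int(np.count_nonzero(net.weights > eps))
        if chi != net.p - n_edges:
            failures.append(float(eps))
    return EulerReport(ok=not failures, n_checked=thresholds.size, failures=failures)
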