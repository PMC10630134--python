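"""Anchor chaining within query chunks.

An *anchor* is an exact seed-k-mer match between a query chunk and the
reference, written as a coordinate pair ``(x, y)``.  A *chain* is a
strictly increasing subsequence of anchors under the partial order
``(x1, y1) ≺ (x2, y2) iff x1 < x2 and y1 < y2``, scored by diagonal
consistency:

    S(i, j) = 20 − |(y_j − y_i) − (x_j − x_i)|

Overlapping k-mers are deliberately not penalized — the chain should
capture every seed arising from homology, since the downstream ANI
estimate counts anchors against seeds.  The optimal-score recurrence

    f(i) = max( max_{j ≺ i} f(j) + S(i, j),  0 )

is evaluated with a banded heuristic: only the ``band_A`` preceding
anchors are scanned, stopping early once the query-coordinate gap
exceeds ``band_B``.  Chains are then recovered by backtracking one
optimal chain per union-find component of the predecessor graph.

Anchors on reverse-strand matches are chained in mirrored reference
coordinates (``y' = contig_length − k − y``) so the same increasing-order
DP applies; callers convert spans back to original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .params import SketchParams

__all__ = [
    "Anchor",
    "Chain",
    "backtrack_chains",
    "chain_anchors_banded",
    "chain_score",
    "collect_anchors",
]


@dataclass(frozen=True, order=True)
class Anchor:
    """Exact seed match: query-chunk offset ``x``, reference offset ``y``.

    ``reverse`` is the relative orientation of the matched seed pair
    (XOR of the two canonical-strand flags).  For reverse anchors ``y``
    may be a mirrored working coordinate during chaining.
    """

    x: int
    y: int
    ref_contig: int = 0
    reverse: bool = False


@dataclass
class Chain:
    """A scored chain of anchors within one chunk, one reference contig
    and one relative orientation."""

    anchors: list[Anchor]
    score: int
    chunk_id: int = 0
    ref_contig: int = 0
    reverse: bool = False

    def __post_init__(self) -> None:
        for a, b in zip(self.anchors, self.anchors[1:]):
            if not (a.x < b.x and a.y < b.y):
                raise ValueError("chain anchors must be strictly increasing in x and y")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def query_interval(self, k: int) -> tuple[int, int]:
        """Half-open chunk-coordinate interval covered by the chain."""
        return self.anchors[0].x, self.anchors[-1].x + k

    def ref_interval(self, k: int, contig_length: int | None = None) -> tuple[int, int]:
        """Half-open reference interval in original contig coordinates.

        For reverse-strand chains ``contig_length`` is required to undo
        the mirrored working coordinate.
        """
        lo, hi = self.anchors[0].y, self.anchors[-1].y + k
        if self.reverse:
            if contig_length is None:
                raise ValueError("contig_length required for reverse-strand span")
            return contig_length - hi, contig_length - lo
        return lo, hi


def collect_anchors(
    chunk_seeds: Sequence[tuple[int, int, bool]],
    ref_seed_map: dict[int, list[tuple[int, int, bool]]],
    params: SketchParams,
) -> list[Anchor]:
    """All anchors between a chunk's seeds and a reference seed map.

    ``chunk_seeds`` are ``(position, hash, reverse)`` sorted by position;
    one anchor is emitted per (chunk seed, reference occurrence) pair
    with matching hash.  Hashes masked out of the reference map produce
    no anchors.  Output is sorted lexicographically by ``(x, y)``.
    """
    anchors: list[Anchor] = []
    for x, h, qstrand in chunk_seeds:
        for contig, y, rstrand in ref_seed_map.get(h, ()):
            anchors.append(Anchor(x=x, y=y, ref_contig=contig, reverse=qstrand != rstrand))
    anchors.sort(key=lambda a: (a.x, a.y))
    return anchors


def chain_score(prev: Anchor, nxt: Anchor) -> int:
    """Diagonal-consistency score for extending a chain from ``prev`` to
    ``nxt``; 20 for collinear anchors, decreasing (possibly negative)
    with the gap-length difference."""
    return 20 - abs((nxt.y - prev.y) - (nxt.x - prev.x))


def chain_anchors_banded(
    anchors: Sequence[Anchor], params: SketchParams
) -> tuple[list[int], list[int | None]]:
    """Banded chaining DP over one (contig, strand) anchor group.

    ``anchors`` must be sorted lexicographically by ``(x, y)``.  Returns
    per-anchor optimal scores ``f`` (all >= 0) and predecessor indices
    (None where the optimal chain starts at the anchor).  Only the
    ``band_A`` immediately preceding anchors are scanned and the scan
    stops once the query gap exceeds ``band_B``, giving O(A·N) work.
    Ties in the predecessor argmax go to the earliest anchor.
    """
    n = len(anchors)
    f: list[int] = [0] * n
    pred: list[int | None] = [None] * n
    band_a = params.effective_band_A
    band_b = params.band_B
    for i in range(n):
        ai = anchors[i]
        best = 0
        best_j: int | None = None
        lo = max(i - band_a, 0)
        for j in range(i - 1, lo - 1, -1):
            aj = anchors[j]
            if ai.x - aj.x > band_b:
                break
            if aj.x < ai.x and aj.y < ai.y:
                s = f[j] + chain_score(aj, ai)
                # descending j: ">=" makes the smallest tied j win
                if s > 0 and s >= best:
                    best, best_j = s, j
        f[i] = best
        pred[i] = best_j
    return f, pred


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def backtrack_chains(
    anchors: Sequence[Anchor],
    f: Sequence[int],
    pred: Sequence[int | None],
    chunk_id: int = 0,
    ref_contig: int = 0,
    reverse: bool = False,
) -> list[Chain]:
    """One optimal chain per disjoint predecessor component.

    Anchors are partitioned by union of (anchor, optimal predecessor)
    pairs; within each component the anchor of maximal ``f`` (earliest
    index on ties) is backtracked.  Returned chains are anchor-disjoint;
    anchors of a component not on its best backtrack path are dropped,
    not emitted as extra chains.
    """
    n = len(anchors)
    if n == 0:
        return []
    uf = _UnionFind(n)
    for i, p in enumerate(pred):
        if p is not None:
            uf.union(i, p)

    best_in_set: dict[int, int] = {}
    for i in range(n):
        root = uf.find(i)
        cur = best_in_set.get(root)
        if cur is None or f[i] > f[cur]:
            best_in_set[root] = i

    chains: list[Chain] = []
    for root in sorted(best_in_set):
        i: int | None = best_in_set[root]
        path: list[Anchor] = []
        while i is not None:
            path.append(anchors[i])
            i = pred[i]
        path.reverse()
        chains.append(
            Chain(
                anchors=path,
                score=f[best_in_set[root]],
                chunk_id=chunk_id,
                ref_contig=ref_contig,
                reverse=reverse,
            )
        )
    return chains
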