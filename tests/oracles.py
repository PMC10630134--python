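"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the chaining
oracle is an exhaustive O(N^2) dynamic program, and the Jaccard/Mash
ANI oracle is a direct full-k-mer-set computation (the classic sketch
estimator whose incompleteness bias the chaining method is designed to
avoid).
"""

from __future__ import annotations

import math

import numpy as np

from chainani.chain import Anchor, chain_score
from chainani.sketch import _window_hashes, _encode_seq


def exhaustive_chain_dp(anchors: list[Anchor]) -> tuple[list[int], list[int | None]]:
    """Unbanded O(N^2) chaining DP; anchors must be sorted lexicographically.

    Ties in the predecessor argmax go to the earliest anchor, matching
    the production tie-break.
    """
    n = len(anchors)
    f: list[int] = [0] * n
    pred: list[int | None] = [None] * n
    for i in range(n):
        best, best_j = 0, None
        for j in range(i):
            if anchors[j].x < anchors[i].x and anchors[j].y < anchors[i].y:
                s = f[j] + chain_score(anchors[j], anchors[i])
                if s > 0 and (s > best or (s == best and (best_j is None or j < best_j))):
                    best, best_j = s, j
        f[i], pred[i] = best, best_j
    return f, pred


def canonical_kmer_set(records: list[tuple[str, str]], k: int) -> set[int]:
    """All canonical k-mer hashes of a genome (no subsampling)."""
    out: set[int] = set()
    for _, seq in records:
        hashes, _, valid = _window_hashes(_encode_seq(seq), k)
        out.update(int(h) for h in hashes[valid])
    return out


def mash_ani(
    records_a: list[tuple[str, str]], records_b: list[tuple[str, str]], k: int = 21
) -> float:
    """Mash-style ANI from the Jaccard index of full canonical k-mer sets.

    ANI = 1 + ln(2J / (1 + J)) / k.  Underestimates true identity when
    one assembly is incomplete, which is exactly the artefact the
    chaining estimator is built to avoid.
    """
    a = canonical_kmer_set(records_a, k)
    b = canonical_kmer_set(records_b, k)
    inter = len(a & b)
    union = len(a | b)
    if inter == 0 or union == 0:
        return 0.0
    j = inter / union
    return 1.0 + math.log(2.0 * j / (1.0 + j)) / k


def jaccard_containment(
    records_a: list[tuple[str, str]], records_b: list[tuple[str, str]], k: int = 21
) -> tuple[float, float, float]:
    """(jaccard, containment of A in B, max containment) on full k-mer sets."""
    a = canonical_kmer_set(records_a, k)
    b = canonical_kmer_set(records_b, k)
    inter = len(a & b)
    return (
        inter / len(a | b),
        inter / len(a),
        inter / min(len(a), len(b)),
    )


def forward_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Plain (non-canonical) 2-bit k-mer codes of every window."""
    codes = _encode_seq(seq).astype(np.uint64)
    m = len(seq) - k + 1
    out = np.zeros(m, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            out = (out << np.uint64(2)) | codes[j : j + m]
    return out


def count_kmer_match_pairs(seq_a: str, seq_b: str, k: int) -> int:
    """Number of position pairs (i, j) with identical forward k-mers."""
    ca = forward_kmer_codes(seq_a, k)
    cb = forward_kmer_codes(seq_b, k)
    ua, na = np.unique(ca, return_counts=True)
    ub, nb = np.unique(cb, return_counts=True)
    common, ia, ib = np.intersect1d(ua, ub, return_indices=True)
    return int((na[ia] * nb[ib]).sum())


def random_anchor_instance(
    rng: np.random.Generator, n_max: int = 200, coord_range: int = 2000
) -> list[Anchor]:
    """A random sorted anchor instance for DP-oracle comparisons."""
    n = int(rng.integers(1, n_max + 1))
    xs = rng.integers(0, coord_range, size=n)
    ys = rng.integers(0, coord_range, size=n)
    anchors = sorted(
        {(int(x), int(y)) for x, y in zip(xs, ys)}
    )
    return [Anchor(x=x, y=y) for x, y in anchors]
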