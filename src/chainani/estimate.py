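"""Genome-pair ANI and aligned-fraction estimation.

The pipeline for one pair of sketches:

1. marker screening (max-containment putative ANI);
2. reference selection — the genome with the larger
   ``total_length × mean_contig_length`` score is the reference, so the
   result is symmetric in argument order;
3. fragmentation of the query into nonoverlapping chunks (20 kb);
4. per-chunk anchoring and banded chaining against the reference;
5. greedy selection of minimally overlapping (orthologous) chains;
6. per-chunk ANI ``(α/M)^(1/k)`` from anchor and seed counts, with a
   truncated variant ``(α/M_LR)^(1/k)`` when only part of a chunk is
   homologous; weighted mean over chunks; aligned fractions; bootstrap
   confidence interval over chunks.

ANI is reported only when the aligned fraction of at least one genome
reaches ``af_threshold``; below that the chains are too sparse for the
estimate to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import Anchor, Chain, backtrack_chains, chain_anchors_banded, collect_anchors
from .params import SketchParams
from .screen import ScreenResult, screen_pair
from .sketch import GenomeSketch

__all__ = [
    "AniResult",
    "Chunk",
    "ChunkStats",
    "aligned_fraction",
    "bootstrap_ci",
    "chunk_ani",
    "combine_ani",
    "compare_pair",
    "fragment_query",
    "homologous_chains",
    "select_orthologous_chains",
    "select_reference",
]


@dataclass(frozen=True)
class Chunk:
    """One query fragment: contig slice ``[start, end)`` with its seeds,
    seed positions re-based to the chunk start."""

    chunk_id: int
    contig: int
    start: int
    end: int
    seeds: tuple[tuple[int, int, bool], ...]

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)


@dataclass
class ChunkStats:
    """Sufficient statistics of one chunk's ANI estimate.

    ``alpha`` — anchors in orthologous chains on the chunk;
    ``m`` — seeds in the chunk;
    ``m_lr`` — seeds between the leftmost and rightmost anchor;
    ``lr_used`` — whether the truncated estimate replaced the full one.
    """

    chunk_id: int
    alpha: int
    m: int
    m_lr: int
    lr_used: bool = False
    ani: float = 0.0

    @property
    def weight(self) -> int:
        return self.m_lr if self.lr_used else self.m


@dataclass
class AniResult:
    """Outcome of one genome-pair comparison.

    ``ani`` is None when the pair failed the marker screen or the
    aligned-fraction gate; ``putative_ani`` (the screening estimate) is
    reported either way.  ``ci90`` is the bootstrap 90% interval,
    present only when enough chunks carry weight.
    """

    query_id: str
    ref_id: str
    ani: float | None
    af_query: float
    af_ref: float
    ci90: tuple[float, float] | None
    n_chunks: int
    putative_ani: float
    aligned_bases: int
    debiased: bool = False
    chunk_stats: list[ChunkStats] = field(default_factory=list, repr=False, compare=False)
    chains: list[Chain] = field(default_factory=list, repr=False, compare=False)


def select_reference(
    sketch_a: GenomeSketch, sketch_b: GenomeSketch
) -> tuple[GenomeSketch, GenomeSketch]:
    """Pick ``(reference, query)`` deterministically and symmetrically.

    The genome with the larger ``total_length × mean_contig_length``
    score becomes the reference; ties break lexicographically on
    genome_id so both call orders give the same assignment.
    """
    score_a = sketch_a.total_length * sketch_a.mean_contig_length
    score_b = sketch_b.total_length * sketch_b.mean_contig_length
    if score_a > score_b:
        return sketch_a, sketch_b
    if score_b > score_a:
        return sketch_b, sketch_a
    if sketch_a.genome_id <= sketch_b.genome_id:
        return sketch_a, sketch_b
    return sketch_b, sketch_a


def fragment_query(query: GenomeSketch, params: SketchParams) -> list[Chunk]:
    """Split every query contig into consecutive ``chunk_size`` windows.

    The trailing partial window of a contig is kept as its own chunk
    (discarding it would bias fragmented assemblies, which have many
    short contigs); very short contigs yield chunks with few or no
    seeds, which simply carry no weight downstream.
    """
    cs = params.chunk_size
    chunks: list[Chunk] = []
    per_contig = query.seeds_by_contig()
    chunk_id = 0
    for contig, length in enumerate(query.contig_lengths):
        seeds = per_contig[contig]
        si = 0
        n_windows = max((length + cs - 1) // cs, 1)
        for w in range(n_windows):
            start, end = w * cs, min((w + 1) * cs, length)
            chunk_seeds: list[tuple[int, int, bool]] = []
            while si < len(seeds) and seeds[si][0] < end:
                pos, h, strand = seeds[si]
                chunk_seeds.append((pos - start, h, strand))
                si += 1
            chunks.append(
                Chunk(chunk_id=chunk_id, contig=contig, start=start, end=end,
                      seeds=tuple(chunk_seeds))
            )
            chunk_id += 1
    return chunks


def homologous_chains(
    chunks: list[Chunk], ref: GenomeSketch, params: SketchParams
) -> list[Chain]:
    """Anchor and chain every chunk against the reference.

    Anchors are grouped by (reference contig, relative orientation) and
    chained within groups only; reverse-orientation groups are chained
    in mirrored reference coordinates ``y' = contig_length − k − y`` so
    inversions and reverse-complement contigs chain under the same
    increasing-order DP.
    """
    k = params.k
    out: list[Chain] = []
    for chunk in chunks:
        if not chunk.seeds:
            continue
        anchors = collect_anchors(chunk.seeds, ref.seeds, params)
        if not anchors:
            continue
        groups: dict[tuple[int, bool], list[Anchor]] = {}
        for a in anchors:
            groups.setdefault((a.ref_contig, a.reverse), []).append(a)
        for (contig, reverse), group in sorted(groups.items()):
            if reverse:
                clen = ref.contig_lengths[contig]
                group = [
                    Anchor(x=a.x, y=clen - k - a.y, ref_contig=contig, reverse=True)
                    for a in group
                ]
            group.sort(key=lambda a: (a.x, a.y))
            f, pred = chain_anchors_banded(group, params)
            out.extend(
                backtrack_chains(group, f, pred, chunk_id=chunk.chunk_id,
                                 ref_contig=contig, reverse=reverse)
            )
    return out


def _interval_overlap(iv: tuple[int, int], union: list[tuple[int, int]]) -> int:
    lo, hi = iv
    return sum(max(0, min(hi, b) - max(lo, a)) for a, b in union)


def _insert_interval(iv: tuple[int, int], union: list[tuple[int, int]]) -> None:
    union.append(iv)
    union.sort()
    merged = [union[0]]
    for a, b in union[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    union[:] = merged


def select_orthologous_chains(
    chains: list[Chain], ref: GenomeSketch, params: SketchParams
) -> list[Chain]:
    """Greedy minimally overlapping chain selection across all chunks.

    Chains are visited in decreasing score order; a chain is selected
    iff it has at least ``min_chain_anchors`` anchors and its
    reference-coordinate span overlaps the union of already-selected
    spans by less than ``overlap_frac`` of its own span.  Overlap is
    measured on the reference because paralogy duplicates reference
    loci regardless of match orientation.
    """
    k = params.k
    candidates = [c for c in chains if c.n_anchors >= params.min_chain_anchors]

    def sort_key(c: Chain):
        a0 = c.anchors[0]
        return (-c.score, c.chunk_id, c.ref_contig, c.reverse, a0.x, a0.y)

    candidates.sort(key=sort_key)
    selected: list[Chain] = []
    union_by_contig: dict[int, list[tuple[int, int]]] = {}
    for c in candidates:
        iv = c.ref_interval(k, ref.contig_lengths[c.ref_contig])
        span = iv[1] - iv[0]
        union = union_by_contig.setdefault(c.ref_contig, [])
        if _interval_overlap(iv, union) < params.overlap_frac * span:
            selected.append(c)
            _insert_interval(iv, union)
    return selected


def chunk_ani(stats: ChunkStats, params: SketchParams, lr_span: int) -> ChunkStats:
    """Per-chunk ANI from anchor and seed counts.

    The base estimate is ``(α/M)^(1/k)``.  When only part of the chunk
    is homologous (incompleteness, structural variation), seeds outside
    the matched region depress the estimate; the truncated form
    ``(α/M_LR)^(1/k)`` — counting only seeds between the flanking
    anchors — replaces it when it exceeds ``lr_ani_gate`` and the
    flanked query span exceeds ``lr_min_span`` bases, i.e. when the
    chains are trustworthy enough to truncate.  Sets ``ani``,
    ``lr_used`` (and hence ``weight``) on the stats and returns them.
    """
    if stats.m <= 0:
        raise ValueError("chunk_ani requires a chunk with at least one seed")
    k = params.k
    base = min(stats.alpha / stats.m, 1.0) ** (1.0 / k)
    stats.lr_used = False
    stats.ani = base
    if stats.alpha > 0 and stats.m_lr > 0:
        ani_lr = min(stats.alpha / stats.m_lr, 1.0) ** (1.0 / k)
        if ani_lr > params.lr_ani_gate and lr_span > params.effective_lr_min_span:
            stats.ani = ani_lr
            stats.lr_used = True
    return stats


def combine_ani(chunk_estimates: list[tuple[float, float]]) -> float:
    """Weighted mean ANI over chunks, weights = seed counts (M or M_LR)."""
    total_w = sum(w for _, w in chunk_estimates)
    if total_w <= 0:
        raise ValueError("no weighted chunks: cannot combine ANI")
    return sum(a * w for a, w in chunk_estimates) / total_w


def aligned_fraction(
    selected_chains: list[Chain],
    query: GenomeSketch,
    ref: GenomeSketch,
    params: SketchParams,
) -> tuple[float, float, int]:
    """Aligned fraction of each genome, from the selected chains.

    Per chain, covered bases = (last − first anchor position) + 2c on
    each genome's own coordinates; the 2c term compensates for seeds
    missed by subsampling near chain edges.  Fractions are the covered
    sums over each genome's total length, capped at 1.  Also returns
    the reference-coordinate covered-base sum (uncapped) used by the
    debias gate.
    """
    two_c = 2 * params.c
    q_bases = 0
    r_bases = 0
    for c in selected_chains:
        q_bases += (c.anchors[-1].x - c.anchors[0].x) + two_c
        r_bases += (c.anchors[-1].y - c.anchors[0].y) + two_c
    af_q = min(q_bases / query.total_length, 1.0) if query.total_length else 0.0
    af_r = min(r_bases / ref.total_length, 1.0) if ref.total_length else 0.0
    return af_q, af_r, r_bases


def bootstrap_ci(
    chunk_estimates: list[tuple[float, float]],
    params: SketchParams,
    rng_seed: int = 0,
) -> tuple[float, float] | None:
    """Chunk-resampling bootstrap 90% interval for the weighted-mean ANI.

    Absent unless strictly more than ``bootstrap_min_chunks`` chunks
    carry weight.  Each of ``bootstrap_iters`` resamples draws chunks
    with replacement and recomputes the weighted mean; the 5th and 95th
    percentiles are returned.  The interval reflects seeding variance
    only — the point estimate never depends on the seed.
    """
    n = len(chunk_estimates)
    if n <= params.bootstrap_min_chunks:
        return None
    anis = np.array([a for a, _ in chunk_estimates])
    ws = np.array([w for _, w in chunk_estimates])
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, n, size=(params.bootstrap_iters, n))
    wsum = ws[idx].sum(axis=1)
    means = (anis[idx] * ws[idx]).sum(axis=1) / wsum
    lo, hi = np.percentile(means, [5.0, 95.0])
    return float(lo), float(hi)


def compare_pair(
    sketch_a: GenomeSketch,
    sketch_b: GenomeSketch,
    params: SketchParams,
    debias_model=None,
    rng_seed: int = 0,
    force_debias: bool | None = None,
) -> AniResult:
    """Full comparison of two sketched genomes.

    Symmetric in argument order: reference selection canonicalizes the
    pair before any asymmetric step.  ``debias_model`` optionally
    applies the learned ANI correction (see :mod:`chainani.debias`);
    ``rng_seed`` affects only the bootstrap interval.
    """
    screen = screen_pair(sketch_a, sketch_b, params)
    ref, query = select_reference(sketch_a, sketch_b)
    putative = screen.putative_ani if not screen.unscreenable else float("nan")

    def empty(n_chunks: int = 0) -> AniResult:
        return AniResult(
            query_id=query.genome_id, ref_id=ref.genome_id, ani=None,
            af_query=0.0, af_ref=0.0, ci90=None, n_chunks=n_chunks,
            putative_ani=putative, aligned_bases=0,
        )

    if not screen.passed:
        return empty()

    chunks = fragment_query(query, params)
    chains = homologous_chains(chunks, ref, params)
    ortho = select_orthologous_chains(chains, ref, params)
    if not ortho:
        return empty()

    by_chunk: dict[int, list[Chain]] = {}
    for c in ortho:
        by_chunk.setdefault(c.chunk_id, []).append(c)

    all_stats: list[ChunkStats] = []
    estimates: list[tuple[float, float]] = []
    for chunk in chunks:
        if chunk.n_seeds == 0 or chunk.chunk_id not in by_chunk:
            continue
        cchains = by_chunk[chunk.chunk_id]
        alpha = sum(ch.n_anchors for ch in cchains)
        x_lo = min(ch.anchors[0].x for ch in cchains)
        x_hi = max(ch.anchors[-1].x for ch in cchains)
        m_lr = sum(1 for x, _, _ in chunk.seeds if x_lo <= x <= x_hi)
        stats = ChunkStats(
            chunk_id=chunk.chunk_id, alpha=min(alpha, chunk.n_seeds),
            m=chunk.n_seeds, m_lr=m_lr,
        )
        chunk_ani(stats, params, lr_span=(x_hi - x_lo) + params.k)
        all_stats.append(stats)
        estimates.append((stats.ani, float(stats.weight)))

    if not estimates:
        return empty()

    ani = combine_ani(estimates)
    af_q, af_r, aligned = aligned_fraction(ortho, query, ref, params)
    if max(af_q, af_r) < params.af_threshold:
        res = empty(n_chunks=len(estimates))
        res.af_query, res.af_ref = af_q, af_r
        res.aligned_bases = aligned
        return res

    ci = bootstrap_ci(estimates, params, rng_seed=rng_seed)
    result = AniResult(
        query_id=query.genome_id, ref_id=ref.genome_id, ani=ani,
        af_query=af_q, af_ref=af_r, ci90=ci, n_chunks=len(estimates),
        putative_ani=putative, aligned_bases=aligned,
        chunk_stats=all_stats, chains=ortho,
    )
    if debias_model is not None:
        from . import debias as _debias

        features = _debias.extract_features(result, ref, query)
        result = _debias.apply_debias(debias_model, result, features, params,
                                      force=force_debias)
    return result
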