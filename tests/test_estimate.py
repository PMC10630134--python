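"""Pipeline orchestration: reference selection, chunking, orthologous
chain selection, per-chunk ANI, weighted combination, AF and bootstrap."""

import numpy as np
import pytest

from chainani.chain import Anchor, Chain
from chainani.estimate import (
    ChunkStats,
    aligned_fraction,
    bootstrap_ci,
    chunk_ani,
    combine_ani,
    compare_pair,
    fragment_query,
    select_orthologous_chains,
    select_reference,
)
from chainani.params import SketchParams
from chainani.sketch import GenomeSketch, sketch_genome
from chainani.simgen import make_pair, mutate, random_genome


def _stub(genome_id: str, contig_lengths: list[int]) -> GenomeSketch:
    return GenomeSketch(
        genome_id=genome_id,
        contig_names=[f"c{i}" for i in range(len(contig_lengths))],
        contig_lengths=contig_lengths,
        seeds={},
        markers=set(),
        params_fingerprint="x",
    )


class TestSelectReference:
    def test_contiguity_beats_total_length(self):
        a = _stub("A", [500_000] * 10)  # 5 Mb total, score 2.5e12
        b = _stub("B", [4_000_000])     # 4 Mb total, score 1.6e13
        ref, query = select_reference(a, b)
        assert ref.genome_id == "B" and query.genome_id == "A"

    def test_tie_broken_lexicographically_and_symmetric(self):
        a = _stub("alpha", [100_000])
        b = _stub("beta", [100_000])
        assert select_reference(a, b) == select_reference(b, a)
        assert select_reference(a, b)[0].genome_id == "alpha"

    def test_argument_order_never_matters(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = _stub("A", list(rng.integers(1_000, 500_000, size=rng.integers(1, 8))))
            b = _stub("B", list(rng.integers(1_000, 500_000, size=rng.integers(1, 8))))
            assert select_reference(a, b) == select_reference(b, a)


class TestFragmentQuery:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (50_000, [(0, 20_000), (20_000, 40_000), (40_000, 50_000)]),
            (20_000, [(0, 20_000)]),
            (300, [(0, 300)]),
        ],
    )
    def test_window_arithmetic(self, params, length, expected):
        sk = sketch_genome([("c", random_genome(length, 1))], params, "g")
        chunks = fragment_query(sk, params)
        assert [(c.start, c.end) for c in chunks] == expected

    def test_seed_coordinates_rebased(self, params):
        sk = sketch_genome([("c", random_genome(50_000, 2))], params, "g")
        chunks = fragment_query(sk, params)
        total = sum(c.n_seeds for c in chunks)
        assert total == sum(len(v) for v in sk.seeds.values())
        for c in chunks:
            for x, _, _ in c.seeds:
                assert 0 <= x < c.end - c.start

    def test_multi_contig_chunk_ids_unique(self, params):
        sk = sketch_genome(
            [("a", random_genome(45_000, 3)), ("b", random_genome(25_000, 4))],
            params, "g",
        )
        chunks = fragment_query(sk, params)
        ids = [c.chunk_id for c in chunks]
        assert ids == sorted(set(ids))
        assert len([c for c in chunks if c.contig == 0]) == 3
        assert len([c for c in chunks if c.contig == 1]) == 2


def _chain(x0, y0, n, score, chunk_id=0, contig=0):
    anchors = [Anchor(x0 + 10 * i, y0 + 10 * i) for i in range(n)]
    return Chain(anchors=anchors, score=score, chunk_id=chunk_id, ref_contig=contig)


class TestOrthologousSelection:
    def test_duplicate_spans_keep_best_score(self, params):
        ref = _stub("r", [100_000])
        a = _chain(0, 1000, 5, score=80)
        b = _chain(0, 1000, 5, score=60, chunk_id=1)
        selected = select_orthologous_chains([b, a], ref, params)
        assert selected == [a]

    def test_two_anchor_chain_never_selected(self, params):
        ref = _stub("r", [100_000])
        assert select_orthologous_chains([_chain(0, 0, 2, score=40)], ref, params) == []

    def test_moderate_overlap_allowed(self, params):
        ref = _stub("r", [100_000])
        a = _chain(0, 1000, 11, score=200)          # ref span [1000, 1115)
        b = _chain(0, 1069, 11, score=150, chunk_id=1)  # overlap 46/115 = 40%
        selected = select_orthologous_chains([a, b], ref, params)
        assert selected == [a, b]

    def test_majority_overlap_rejected(self, params):
        ref = _stub("r", [100_000])
        a = _chain(0, 1000, 11, score=200)
        b = _chain(0, 1040, 11, score=150, chunk_id=1)  # overlap 75/115 = 65%
        selected = select_orthologous_chains([a, b], ref, params)
        assert selected == [a]


class TestChunkAni:
    def test_perfect_chunk(self, params):
        s = chunk_ani(ChunkStats(0, alpha=160, m=160, m_lr=160), params, lr_span=19_000)
        assert s.ani == pytest.approx(1.0)

    def test_zero_anchors(self, params):
        s = chunk_ani(ChunkStats(0, alpha=0, m=160, m_lr=0), params, lr_span=0)
        assert s.ani == 0.0 and not s.lr_used

    def test_closed_form(self, params):
        s = ChunkStats(0, alpha=80, m=100, m_lr=80)
        # LR variant would give 1.0 > gate but span below 4c disables it
        chunk_ani(s, params, lr_span=400)
        assert s.ani == pytest.approx(0.8 ** (1 / 15), abs=1e-12)
        assert s.ani == pytest.approx(0.9852338677990639, abs=1e-10)
        assert not s.lr_used and s.weight == 100

    def test_lr_heuristic_truncates_partial_chunk(self, params):
        # half the chunk unaligned: α/M low but α/M_LR high over a long span
        s = ChunkStats(0, alpha=78, m=160, m_lr=80)
        chunk_ani(s, params, lr_span=10_000)
        assert s.lr_used and s.weight == 80
        assert s.ani == pytest.approx((78 / 80) ** (1 / 15))

    def test_empty_chunk_rejected(self, params):
        with pytest.raises(ValueError):
            chunk_ani(ChunkStats(0, alpha=0, m=0, m_lr=0), params, lr_span=0)


class TestCombineAni:
    def test_single_chunk(self):
        assert combine_ani([(0.97, 42.0)]) == pytest.approx(0.97)

    def test_weighted_mean(self):
        assert combine_ani([(0.90, 10.0), (1.00, 30.0)]) == pytest.approx(0.975)

    def test_constant_chunks(self):
        assert combine_ani([(0.93, w) for w in (5.0, 10.0, 80.0)]) == pytest.approx(0.93)

    def test_no_weight_errors(self):
        with pytest.raises(ValueError, match="no weighted chunks"):
            combine_ani([])


class TestAlignedFraction:
    def test_no_chains(self, params):
        q, r = _stub("q", [50_000]), _stub("r", [50_000])
        assert aligned_fraction([], q, r, params) == (0.0, 0.0, 0)

    def test_edge_compensation_term(self, params):
        q, r = _stub("q", [10_000]), _stub("r", [100_000])
        ch = _chain(0, 500, 11, score=200)  # spans 100 bases on both axes
        af_q, af_r, bases = aligned_fraction([ch], q, r, params)
        expected = 100 + 2 * params.c
        assert bases == expected
        assert af_q == pytest.approx(expected / 10_000)
        assert af_r == pytest.approx(expected / 100_000)

    def test_capped_at_one(self, params):
        q, r = _stub("q", [200]), _stub("r", [200])
        ch = _chain(0, 0, 4, score=60)
        af_q, af_r, _ = aligned_fraction([ch], q, r, params)
        assert af_q == 1.0 and af_r == 1.0


class TestBootstrap:
    def test_absent_at_ten_chunks(self, params):
        est = [(0.97, 10.0)] * 10
        assert bootstrap_ci(est, params, rng_seed=1) is None

    def test_zero_width_on_constant_chunks(self, params):
        est = [(0.97, float(w)) for w in range(1, 51)]
        lo, hi = bootstrap_ci(est, params, rng_seed=2)
        assert lo == pytest.approx(0.97) and hi == pytest.approx(0.97)

    def test_reproducible_and_seed_sensitive(self, params):
        rng = np.random.default_rng(5)
        est = [(float(a), float(w)) for a, w in
               zip(rng.normal(0.95, 0.01, 40), rng.integers(50, 200, 40))]
        assert bootstrap_ci(est, params, 7) == bootstrap_ci(est, params, 7)
        assert bootstrap_ci(est, params, 7) != bootstrap_ci(est, params, 8)

    def test_interval_brackets_point_estimate(self, params):
        rng = np.random.default_rng(6)
        est = [(float(a), 100.0) for a in rng.normal(0.95, 0.005, 60)]
        lo, hi = bootstrap_ci(est, params, 3)
        assert lo <= combine_ani(est) <= hi


class TestComparePair:
    def test_self_comparison(self, params):
        sk = sketch_genome([("c", random_genome(400_000, 9))], params, "g")
        res = compare_pair(sk, sk, params)
        assert res.ani == pytest.approx(1.0)
        assert res.af_query > 0.98 and res.af_ref > 0.98
        assert res.putative_ani == pytest.approx(1.0)

    def test_unrelated_genomes_no_ani(self, params):
        a = sketch_genome([("c", random_genome(500_000, 10))], params, "a")
        b = sketch_genome([("c", random_genome(500_000, 11))], params, "b")
        res = compare_pair(a, b, params)
        assert res.ani is None

    def test_symmetry_bit_identical(self, params):
        for rep in range(4):
            base, query, _ = make_pair(150_000, 0.02 + 0.01 * rep, rng_seed=rep)
            a = sketch_genome(base, params, "a")
            b = sketch_genome(query, params, "b")
            r1 = compare_pair(a, b, params, rng_seed=5)
            r2 = compare_pair(b, a, params, rng_seed=5)
            assert r1 == r2

    def test_known_divergence_recovered(self, params):
        base, query, _ = make_pair(400_000, 0.04, rng_seed=21)
        a = sketch_genome(base, params, "a")
        b = sketch_genome(query, params, "b")
        res = compare_pair(a, b, params)
        assert res.ani == pytest.approx(0.96, abs=0.005)
        assert res.ci90 is not None and res.n_chunks == 20

    def test_af_monotone_under_reference_deletion(self, params):
        # removing reference sequence can only decrease af_ref
        genome = random_genome(300_000, 13)
        full = sketch_genome([("c", genome)], params, "full")
        prev = 1.01
        for frac in (1.0, 0.7, 0.4):
            part = sketch_genome(
                [("c", genome[: int(300_000 * frac)])], params, "part"
            )
            res = compare_pair(full, part, params)
            af_ref_full = res.af_ref if res.ref_id == "full" else res.af_query
            assert af_ref_full <= prev + 1e-9
            prev = af_ref_full
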