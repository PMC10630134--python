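"""FracMinHash sketching of genome assemblies.

A genome is reduced to two k-mer collections:

* **seeds** — a relatively dense set (expected density ``1/c``) of short
  k-mers (``k`` = 15 by default) whose positions are retained; these are
  the substrate for anchoring and chaining.
* **markers** — a very sparse set (density ``1/marker_c``) of longer
  k-mers (21 by default) used only by the max-containment screening
  filter; positions are not needed.

Both collections are selected by the FracMinHash rule: a window is kept
iff the 64-bit hash of its canonical form falls below ``2**64 / rate``.
Selection is a pointwise predicate on the hash, so the sketch of a
genome is independent of any other genome and of window order.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .params import SketchParams

__all__ = [
    "AmbiguousKmerError",
    "GenomeSketch",
    "canonical_kmer_hash",
    "fracminhash_select",
    "fracminhash_threshold",
    "mask_repetitive_seeds",
    "read_fasta",
    "sketch_genome",
    "sketch_fasta",
]

_HASH_SPACE = 1 << 64

# base -> 2-bit code; 255 marks anything outside upper-case ACGT after
# upper-casing (N, IUPAC codes, gaps): every window covering such a base
# is voided.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _ENCODE[_b] = _v
    _ENCODE[_b + 32] = _v  # lower case

_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_S33 = np.uint64(33)


class AmbiguousKmerError(ValueError):
    """Raised when a k-mer contains a non-ACGT character."""


def _mix64(h: np.ndarray) -> np.ndarray:
    """Invertible 64-bit finalizer (murmur3 fmix64) applied elementwise."""
    h = h.copy()
    with np.errstate(over="ignore"):
        h ^= h >> _S33
        h *= _M1
        h ^= h >> _S33
        h *= _M2
        h ^= h >> _S33
    return h


def _encode_seq(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def _window_hashes(codes: np.ndarray, k: int):
    """Canonical hashes for all length-``k`` windows of an encoded contig.

    Returns ``(hashes, strands, valid)`` — arrays of length ``n - k + 1``.
    ``strands`` is True where the reverse complement was the canonical
    orientation; ``valid`` is False for windows covering a non-ACGT base.
    """
    n = codes.shape[0]
    m = n - k + 1
    if m <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)

    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0

    a = np.where(codes > 3, 0, codes).astype(np.uint64)
    comp = np.uint64(3) - a
    two = np.uint64(2)

    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << two) | a[j : j + m]
        for j in range(k - 1, -1, -1):
            rev = (rev << two) | comp[j : j + m]

    strands = rev < fwd
    canonical = np.where(strands, rev, fwd)
    return _mix64(canonical), strands, valid


def canonical_kmer_hash(kmer: str) -> tuple[int, bool]:
    """Hash a single k-mer in canonical (strand-independent) form.

    The k-mer and its reverse complement are 2-bit encoded (A<C<G<T) and
    the numerically smaller encoding is passed through a fixed invertible
    64-bit mixer.  Returns ``(hash, reverse_strand)`` where the flag is
    True iff the reverse complement won canonicalization.

    Raises
    ------
    AmbiguousKmerError
        If the k-mer contains any character outside ACGT (callers skip
        such windows).
    """
    codes = _encode_seq(kmer)
    if (codes > 3).any():
        raise AmbiguousKmerError(f"k-mer contains non-ACGT characters: {kmer!r}")
    hashes, strands, _ = _window_hashes(codes, len(kmer))
    return int(hashes[0]), bool(strands[0])


def fracminhash_threshold(rate: float) -> int:
    """Selection cutoff ``floor(2**64 / rate)`` on the 64-bit hash space."""
    if rate < 1:
        raise ValueError("subsampling rate must be >= 1")
    if isinstance(rate, (int, np.integer)):
        return _HASH_SPACE // int(rate)
    return int(_HASH_SPACE / rate)


def fracminhash_select(hash_value: int, rate: float) -> bool:
    """FracMinHash predicate: keep a k-mer iff its hash < ``2**64 / rate``.

    A pure pointwise threshold test; the expected selected fraction of
    uniformly hashed k-mers is ``1/rate``.
    """
    return int(hash_value) < fracminhash_threshold(rate)


@dataclass
class GenomeSketch:
    """Sketched representation of one genome assembly.

    ``seeds`` maps each selected seed hash to its occurrence list of
    ``(contig_index, position, reverse_strand)`` tuples, positions being
    0-based leftmost-window coordinates, strictly increasing within a
    contig.  ``markers`` is the sparse marker-hash set used for
    screening.
    """

    genome_id: str
    contig_names: list[str]
    contig_lengths: list[int]
    seeds: dict[int, list[tuple[int, int, bool]]]
    markers: set[int]
    params_fingerprint: str

    _seeds_by_contig: list[list[tuple[int, int, bool]]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths)

    @property
    def mean_contig_length(self) -> float:
        return self.total_length / len(self.contig_lengths) if self.contig_lengths else 0.0

    def seeds_by_contig(self) -> list[list[tuple[int, int, bool]]]:
        """Per-contig seed lists ``(position, hash, reverse_strand)``, sorted
        by position.  Computed lazily from the hash-keyed map and cached."""
        if self._seeds_by_contig is None:
            per: list[list[tuple[int, int, bool]]] = [[] for _ in self.contig_names]
            for h, occs in self.seeds.items():
                for contig, pos, strand in occs:
                    per[contig].append((pos, h, strand))
            for lst in per:
                lst.sort()
            self._seeds_by_contig = per
        return self._seeds_by_contig


def mask_repetitive_seeds(
    seeds: dict[int, list[tuple[int, int, bool]]], params: SketchParams
) -> dict[int, list[tuple[int, int, bool]]]:
    """Drop seed hashes occurring more than ``band_B // c`` times genome-wide.

    With defaults (B=2500, c=125) the cutoff is 20 occurrences: a hash
    seen 21+ times across all contigs is removed entirely.  Repetitive
    seeds at the default short ``k`` would otherwise flood the chaining
    stage with spurious anchors.
    """
    cutoff = params.effective_mask_threshold
    return {h: occs for h, occs in seeds.items() if len(occs) <= cutoff}


def sketch_genome(
    fasta_records: Sequence[tuple[str, str]],
    params: SketchParams,
    genome_id: str = "",
) -> GenomeSketch:
    """Sketch a genome given as ``(name, sequence)`` records.

    Seeds are all k-mer windows whose canonical hash passes FracMinHash
    selection at rate ``c`` (after repetitive-seed masking); markers are
    the canonical marker-k-mer hashes passing selection at rate
    ``marker_c``.  Windows containing non-ACGT characters are skipped.
    """
    if not fasta_records:
        raise ValueError(f"no sequence records in genome {genome_id!r}")

    # inclusive cutoffs: select iff h < T, i.e. h <= T-1 (T=2^64 at rate 1)
    seed_cut = np.uint64(fracminhash_threshold(params.c) - 1)
    marker_cut = np.uint64(fracminhash_threshold(params.marker_c) - 1)

    contig_names: list[str] = []
    contig_lengths: list[int] = []
    seeds: dict[int, list[tuple[int, int, bool]]] = {}
    markers: set[int] = set()
    any_window = False

    for contig_idx, (name, seq) in enumerate(fasta_records):
        contig_names.append(name)
        contig_lengths.append(len(seq))
        codes = _encode_seq(seq)

        hashes, strands, valid = _window_hashes(codes, params.k)
        keep = valid & (hashes <= seed_cut)
        any_window = any_window or valid.any()
        for pos in np.flatnonzero(keep):
            h = int(hashes[pos])
            seeds.setdefault(h, []).append((contig_idx, int(pos), bool(strands[pos])))

        mh, _, mvalid = _window_hashes(codes, params.marker_k)
        mkeep = mvalid & (mh <= marker_cut)
        markers.update(int(x) for x in mh[mkeep])

    if not any_window:
        warnings.warn(
            f"genome {genome_id!r}: no valid k-mer windows (all contigs shorter "
            f"than k or all-ambiguous); sketch is empty",
            stacklevel=2,
        )

    seeds = mask_repetitive_seeds(seeds, params)
    return GenomeSketch(
        genome_id=genome_id,
        contig_names=contig_names,
        contig_lengths=contig_lengths,
        seeds=seeds,
        markers=markers,
        params_fingerprint=params.fingerprint(),
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzip-compressed) multi-record FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError(f"no sequence records in FASTA file {path}")
    return records


def sketch_fasta(path: str | Path, params: SketchParams) -> GenomeSketch:
    """Read and sketch a FASTA file, using the path as the genome id."""
    return sketch_genome(read_fasta(path), params, genome_id=str(path))
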