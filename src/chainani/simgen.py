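"""Synthetic genome pairs with known divergence and assembly quality.

The mutation model is the standard independent-substitution model: each
base of a genome ``G`` is changed to one of the three other letters with
probability θ, giving ``G'`` with true ANI ``1 − θ``.  On top of that,
:func:`degrade` emulates the artefacts of metagenome-assembled genomes:

* **fragmentation** — random breakpoints chosen so the realized contig
  N50 approximates a target;
* **incompleteness** — random contigs dropped until only a target
  fraction of the sequence remains;
* **contamination** — unrelated contigs (from an independent random
  genome) appended, as foreign-bin contamination would.

Every operation is reproducible from an integer seed and returns exact
truth bookkeeping (realized mismatch count, retained fraction, realized
N50), so estimator bias can be measured against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimSpec",
    "Truth",
    "degrade",
    "make_pair",
    "mutate",
    "n50",
    "random_genome",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {65: 0, 67: 1, 71: 2, 84: 3}

# For k uniform random breakpoints, fragment lengths behave like uniform
# spacings (approximately exponential for large k); the length-weighted
# median of an exponential with mean m is ~1.678 m, so we fragment into
# ~1.678 L / N50 pieces to hit a target N50.
_N50_EXP_FACTOR = 1.678


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one degraded synthetic assembly."""

    base_length: int = 1_000_000
    theta: float = 0.0
    target_n50: int | None = None
    completeness: float = 1.0
    contamination: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0, 1]")
        if self.contamination < 0.0:
            raise ValueError("contamination must be >= 0")


@dataclass(frozen=True)
class Truth:
    """Ground truth for one simulated assembly."""

    theta: float
    realized_mismatches: int
    retained_fraction: float
    realized_n50: int
    contamination_bases: int
    n_contigs: int


def random_genome(length: int, rng_seed: int | np.random.Generator = 0) -> str:
    """An i.i.d. uniform-ACGT sequence, reproducible by seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate(
    sequence: str, theta: float, rng_seed: int | np.random.Generator = 0
) -> tuple[str, int]:
    """Substitute each base independently with probability ``theta``.

    A substituted base is always changed to a *different* letter, so the
    realized mismatch count (returned for truth bookkeeping) equals the
    Hamming distance to the input.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    codes = _encode(np.frombuffer(sequence.encode("ascii"), dtype=np.uint8))
    hit = rng.random(codes.shape[0]) < theta
    n_hit = int(hit.sum())
    shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
    out = codes.copy()
    out[hit] = (codes[hit] + shift) % 4
    return _ALPHABET[out].tobytes().decode("ascii"), n_hit


def _encode(codes: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for b, v in _DECODE.items():
        table[b] = v
    return table[codes]


def n50(lengths: list[int]) -> int:
    """Contig length at which half the assembly bases are in contigs at
    least that long."""
    if not lengths:
        return 0
    arr = sorted(lengths, reverse=True)
    half = sum(arr) / 2.0
    acc = 0
    for v in arr:
        acc += v
        if acc >= half:
            return v
    return arr[-1]


def _fragment(seq: str, target_n50: int | None, rng: np.random.Generator) -> list[str]:
    if target_n50 is None or target_n50 >= len(seq):
        return [seq]
    n_frag = max(int(round(_N50_EXP_FACTOR * len(seq) / target_n50)), 1)
    if n_frag == 1:
        return [seq]
    cuts = np.sort(rng.choice(np.arange(1, len(seq)), size=n_frag - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(seq)]
    return [seq[a:b] for a, b in zip(bounds, bounds[1:])]


def degrade(genome: str, spec: SimSpec) -> tuple[list[tuple[str, str]], Truth]:
    """Fragment, subsample and contaminate a genome per ``spec``.

    Returns FASTA-style ``(name, sequence)`` records and the realized
    :class:`Truth`.  Contamination contigs are drawn from an independent
    random genome (evolutionarily unrelated) of length
    ``contamination × retained bases``, fragmented at the same target
    N50.
    """
    rng = np.random.default_rng(spec.rng_seed)
    contigs = _fragment(genome, spec.target_n50, rng)

    if spec.completeness < 1.0:
        order = rng.permutation(len(contigs))
        target = spec.completeness * len(genome)
        kept_idx: list[int] = []
        acc = 0
        for i in order:
            kept_idx.append(int(i))
            acc += len(contigs[i])
            if acc >= target:
                break
        if not kept_idx:
            raise ValueError("completeness so low that no contig survives")
        kept_idx.sort()
        contigs = [contigs[i] for i in kept_idx]

    retained = sum(map(len, contigs))
    records = [(f"contig_{i}", s) for i, s in enumerate(contigs)]

    contam_bases = 0
    if spec.contamination > 0.0:
        contam_len = int(round(spec.contamination * retained))
        if contam_len > 0:
            foreign = random_genome(contam_len, rng)
            for j, s in enumerate(_fragment(foreign, spec.target_n50, rng)):
                records.append((f"contam_{j}", s))
                contam_bases += len(s)

    return records, Truth(
        theta=spec.theta,
        realized_mismatches=0,
        retained_fraction=retained / len(genome),
        realized_n50=n50([len(s) for s in contigs]),
        contamination_bases=contam_bases,
        n_contigs=len(records),
    )


def make_pair(
    length: int,
    theta: float,
    rng_seed: int = 0,
    query_spec: SimSpec | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], Truth]:
    """Convenience generator: a random base genome and its mutated,
    optionally degraded partner.

    The first genome is returned intact as a single contig; the second
    is mutated at rate ``theta`` and degraded per ``query_spec`` (whose
    own ``theta``/``base_length`` fields are ignored in favour of the
    arguments).  True ANI of the pair is ``1 − theta``.
    """
    rng = np.random.default_rng(rng_seed)
    base = random_genome(length, rng)
    mutated, n_mut = mutate(base, theta, rng)
    spec = query_spec or SimSpec()
    spec = SimSpec(
        base_length=length, theta=theta, target_n50=spec.target_n50,
        completeness=spec.completeness, contamination=spec.contamination,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )
    records, truth = degrade(mutated, spec)
    truth = Truth(
        theta=theta, realized_mismatches=n_mut,
        retained_fraction=truth.retained_fraction,
        realized_n50=truth.realized_n50,
        contamination_bases=truth.contamination_bases,
        n_contigs=truth.n_contigs,
    )
    return [("base_0", base)], records, truth
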