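"""Parameter bundle governing sketching, chaining and ANI estimation.

Every genome comparison is parameterized by exactly one :class:`SketchParams`
instance.  Two sketches may only be compared when their parameter
fingerprints agree, since seed sets produced at different ``k`` or ``c``
are not comparable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class SketchParams:
    """Tunable parameters for sketching and comparison.

    Parameters
    ----------
    k
        Seed k-mer length used for anchoring and chaining.
    c
        Seed subsampling rate: an expected ``1/c`` fraction of k-mer
        windows is selected as seeds.
    marker_k
        Marker k-mer length (called l-mers in the screening context);
        must exceed ``k``.
    marker_c
        Marker subsampling rate; much sparser than the seed rate.
    chunk_size
        Query fragmentation window in bases.
    band_B
        Maximum query-coordinate gap (bases) between chained anchors.
    band_A
        Maximum number of predecessor anchors scanned in the chaining DP.
        Defaults to ``band_B // c`` with a floor of 1.
    mask_threshold
        Seeds occurring more than this many times in one genome are
        masked.  Defaults to ``band_B // c`` with a floor of 1.
    marker_ani_threshold
        Screening gate: genome pairs whose marker-based ANI estimate is
        at or below this fraction are not compared further.
    af_threshold
        Minimum aligned fraction (of either genome) required to report
        an ANI.
    lr_ani_gate
        Minimum flanked-region ANI for the truncated per-chunk estimate
        to replace the whole-chunk estimate.
    lr_min_span
        Minimum base span between flanking anchors for the truncated
        estimate.  Defaults to ``4 * c``.
    min_chain_anchors
        Minimum anchors per chain for orthologous-chain selection.
    overlap_frac
        Maximum reference-span overlap (as a fraction of a candidate
        chain's span) tolerated during greedy orthologous selection.
    bootstrap_iters
        Bootstrap resamples for the ANI confidence interval.
    bootstrap_min_chunks
        The CI is produced only when strictly more chunks than this
        carry weight.
    debias_ani_gate, debias_min_aligned, debias_auto_c
        Gates for the learned ANI correction: it applies only above this
        ANI, above this many aligned bases, and (by default) only when
        ``c`` is at least ``debias_auto_c``.
    """

    k: int = 15
    c: int = 125
    marker_k: int = 21
    marker_c: int = 1000
    chunk_size: int = 20_000
    band_B: int = 2500
    band_A: int | None = None
    mask_threshold: int | None = None
    marker_ani_threshold: float = 0.80
    af_threshold: float = 0.15
    lr_ani_gate: float = 0.950
    lr_min_span: int | None = None
    min_chain_anchors: int = 3
    overlap_frac: float = 0.50
    bootstrap_iters: int = 100
    bootstrap_min_chunks: int = 10
    debias_ani_gate: float = 0.90
    debias_min_aligned: int = 150_000
    debias_auto_c: int = 70

    def __post_init__(self) -> None:
        if not self.k < self.marker_k:
            raise ValueError(f"seed length k={self.k} must be < marker length {self.marker_k}")
        if not self.c < self.marker_c:
            raise ValueError(f"seed rate c={self.c} must be < marker rate {self.marker_c}")
        if self.c < 1 or self.marker_c < 1:
            raise ValueError("subsampling rates must be >= 1")
        for name in ("marker_ani_threshold", "af_threshold", "lr_ani_gate",
                     "overlap_frac", "debias_ani_gate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.chunk_size <= 2 * self.k:
            raise ValueError("chunk_size must exceed 2k")

    @property
    def effective_band_A(self) -> int:
        if self.band_A is not None:
            return max(self.band_A, 1)
        return max(self.band_B // self.c, 1)

    @property
    def effective_mask_threshold(self) -> int:
        if self.mask_threshold is not None:
            return max(self.mask_threshold, 1)
        return max(self.band_B // self.c, 1)

    @property
    def effective_lr_min_span(self) -> int:
        if self.lr_min_span is not None:
            return self.lr_min_span
        return 4 * self.c

    def fingerprint(self) -> str:
        """Digest of every field that affects sketch or comparison content."""
        payload = ";".join(f"{f.name}={getattr(self, f.name)!r}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Preset names exposed by the CLI, mapping to the seed subsampling rate.
#: "slow" favours accuracy on very fragmented/distant genomes, "fast"
#: trades sensitivity for speed on similar, contiguous genomes.
PRESETS: dict[str, int] = {"slow": 30, "medium": 70, "fast": 200, "default": 125}


def params_for_preset(preset: str, c: int | None = None, **overrides) -> SketchParams:
    """Build :class:`SketchParams` from a named preset.

    An explicit ``c`` always wins over the preset's value.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    eff_c = c if c is not None else PRESETS[preset]
    return SketchParams(c=eff_c, **overrides)
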