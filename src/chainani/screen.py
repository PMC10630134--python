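"""Max-containment marker screening.

Before the (comparatively costly) chaining stage, genome pairs are
filtered by an ANI estimate computed from the sparse marker sets alone:

    ANI_FMH = (|A ∩ B| / min(|A|, |B|)) ** (1 / marker_k)

The max-containment index in the base is robust to one-sided
incompleteness — if one assembly is a subset of the other, the smaller
marker set is still (nearly) fully contained.  Pairs with
ANI_FMH <= 80% (default) are not chained; the marker estimate is a
conservative underestimate in that regime.

For many-vs-many comparisons an inverted index (marker hash -> genomes
carrying it) makes screening time depend on the number of *similar*
genomes rather than on the database size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .params import SketchParams
from .sketch import GenomeSketch

__all__ = [
    "MarkerIndex",
    "ScreenResult",
    "ani_fmh",
    "build_marker_index",
    "max_containment",
    "screen_pair",
]


def max_containment(markers_a: set[int], markers_b: set[int]) -> float:
    """Max-containment index ``|A ∩ B| / min(|A|, |B|)`` of two marker sets."""
    if not markers_a or not markers_b:
        raise ValueError("max_containment requires two non-empty marker sets")
    inter = len(markers_a & markers_b)
    return inter / min(len(markers_a), len(markers_b))


def ani_fmh(containment: float, marker_k: int) -> float:
    """ANI implied by a containment index under independent mutation.

    A marker survives mutation iff all ``marker_k`` of its bases do, so
    containment ≈ ANI ** marker_k and ANI_FMH = containment ** (1/marker_k).
    """
    if not 0.0 <= containment <= 1.0:
        raise ValueError(f"containment {containment} outside [0, 1]")
    if marker_k < 1:
        raise ValueError("marker_k must be >= 1")
    return containment ** (1.0 / marker_k)


@dataclass(frozen=True)
class ScreenResult:
    passed: bool
    putative_ani: float
    #: True when a genome had no markers and the filter could not be applied.
    unscreenable: bool = False


def screen_pair(
    sketch_a: GenomeSketch, sketch_b: GenomeSketch, params: SketchParams
) -> ScreenResult:
    """Marker-based pre-filter for one genome pair.

    Passes iff ANI_FMH strictly exceeds ``marker_ani_threshold``.  A
    genome with no markers (all contigs shorter than the marker length)
    cannot be screened: the pair passes with a warning so the full
    comparison can still decide.
    """
    if sketch_a.params_fingerprint != sketch_b.params_fingerprint:
        raise ValueError(
            "cannot compare sketches with different parameter fingerprints: "
            f"{sketch_a.genome_id!r} vs {sketch_b.genome_id!r}"
        )
    if not sketch_a.markers or not sketch_b.markers:
        warnings.warn(
            f"genome pair ({sketch_a.genome_id!r}, {sketch_b.genome_id!r}): "
            "empty marker set, screening skipped",
            stacklevel=2,
        )
        return ScreenResult(passed=True, putative_ani=float("nan"), unscreenable=True)
    cont = max_containment(sketch_a.markers, sketch_b.markers)
    putative = ani_fmh(cont, params.marker_k)
    return ScreenResult(passed=putative > params.marker_ani_threshold, putative_ani=putative)


class MarkerIndex:
    """Inverted index from marker hash to the genomes containing it."""

    def __init__(self, sketches: list[GenomeSketch]):
        if not sketches:
            raise ValueError("MarkerIndex requires at least one sketch")
        self.table: dict[int, list[int]] = {}
        self.genome_marker_counts: list[int] = []
        for gi, sk in enumerate(sketches):
            self.genome_marker_counts.append(len(sk.markers))
            for m in sk.markers:
                self.table.setdefault(m, []).append(gi)

    def intersection_counts(self, markers: set[int]) -> dict[int, int]:
        """Exact ``|A ∩ B|`` against every indexed genome sharing a marker.

        Genomes sharing no marker with the query are absent from the
        result, which is what makes index-based screening fast on
        diverse databases.
        """
        counts: dict[int, int] = {}
        for m in markers:
            for gi in self.table.get(m, ()):
                counts[gi] = counts.get(gi, 0) + 1
        return counts

    def screen(
        self, query: GenomeSketch, params: SketchParams
    ) -> dict[int, ScreenResult]:
        """Screen a query against every indexed genome.

        Returns results only for genomes with a non-zero marker
        intersection; all other pairs fail with putative ANI 0 by
        construction.
        """
        if not query.markers:
            warnings.warn(
                f"genome {query.genome_id!r}: empty marker set, cannot screen via index",
                stacklevel=2,
            )
            return {}
        out: dict[int, ScreenResult] = {}
        qn = len(query.markers)
        for gi, inter in self.intersection_counts(query.markers).items():
            denom = min(qn, self.genome_marker_counts[gi])
            if denom == 0:
                continue
            putative = ani_fmh(inter / denom, params.marker_k)
            out[gi] = ScreenResult(
                passed=putative > params.marker_ani_threshold, putative_ani=putative
            )
        return out


def build_marker_index(sketches: list[GenomeSketch]) -> MarkerIndex:
    """Build the inverted marker index over a sketch collection."""
    return MarkerIndex(sketches)
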