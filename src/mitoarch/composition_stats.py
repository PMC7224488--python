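"""Base composition, A+T/G+C content and strand-skew statistics.

Skews follow the standard strand-asymmetry definitions
``AT-skew = (A - T) / (A + T)`` and ``GC-skew = (G - C) / (G + C)``.
Ambiguity codes are counted in ``n_other`` and excluded from skew
denominators.  Reporting precision mirrors the usual convention of the
field: percentages to 2 decimals, skews to 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome_io import AnnotatedGenome, GeneFeature, extract_feature, extract_region

__all__ = [
    "CompositionStats",
    "CodonPositionComposition",
    "skew",
    "base_composition",
    "composition_from_counts",
    "region_composition",
    "codon_position_composition",
]


def skew(x_count: int, y_count: int) -> float | None:
    """``(x - y) / (x + y)``; ``None`` when the denominator is zero."""
    if x_count < 0 or y_count < 0:
        raise ValueError("counts must be non-negative")
    total = x_count + y_count
    if total == 0:
        return None
    return (x_count - y_count) / total


@dataclass(frozen=True)
class CompositionStats:
    n_A: int
    n_T: int
    n_G: int
    n_C: int
    n_other: int = 0

    @property
    def total(self) -> int:
        return self.n_A + self.n_T + self.n_G + self.n_C + self.n_other

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total

    @property
    def pct_A(self) -> float:
        return self._pct(self.n_A)

    @property
    def pct_T(self) -> float:
        return self._pct(self.n_T)

    @property
    def pct_G(self) -> float:
        return self._pct(self.n_G)

    @property
    def pct_C(self) -> float:
        return self._pct(self.n_C)

    @property
    def at_content(self) -> float:
        return self._pct(self.n_A + self.n_T)

    @property
    def gc_content(self) -> float:
        return self._pct(self.n_G + self.n_C)

    @property
    def at_skew(self) -> float | None:
        return skew(self.n_A, self.n_T)

    @property
    def gc_skew(self) -> float | None:
        return skew(self.n_G, self.n_C)

    def __add__(self, other: "CompositionStats") -> "CompositionStats":
        return CompositionStats(
            self.n_A + other.n_A,
            self.n_T + other.n_T,
            self.n_G + other.n_G,
            self.n_C + other.n_C,
            self.n_other + other.n_other,
        )

    def rounded(self) -> dict[str, float | int | None]:
        """Report-style dict: percentages at 2 decimals, skews at 4."""
        at_sk, gc_sk = self.at_skew, self.gc_skew
        return {
            "size": self.total,
            "n_A": self.n_A,
            "n_T": self.n_T,
            "n_G": self.n_G,
            "n_C": self.n_C,
            "n_other": self.n_other,
            "pct_A": round(self.pct_A, 2),
            "pct_T": round(self.pct_T, 2),
            "pct_G": round(self.pct_G, 2),
            "pct_C": round(self.pct_C, 2),
            "at_content": round(self.at_content, 2),
            "gc_content": round(self.gc_content, 2),
            "at_skew": None if at_sk is None else round(at_sk, 4),
            "gc_skew": None if gc_sk is None else round(gc_sk, 4),
        }


def composition_from_counts(
    n_A: int, n_T: int, n_G: int, n_C: int, n_other: int = 0
) -> CompositionStats:
    stats = CompositionStats(n_A, n_T, n_G, n_C, n_other)
    if stats.total == 0:
        raise ValueError("empty composition")
    return stats


def base_composition(seq: str) -> CompositionStats:
    """Count bases of ``seq`` (upper-cased, U treated as T)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    n_a, n_t = s.count("A"), s.count("T")
    n_g, n_c = s.count("G"), s.count("C")
    return CompositionStats(n_a, n_t, n_g, n_c, len(s) - n_a - n_t - n_g - n_c)


def region_composition(
    genome: AnnotatedGenome,
    region: GeneFeature | tuple[int, int] | None = None,
    strand_aware: bool = False,
) -> CompositionStats:
    """Composition of a feature or coordinate range of ``genome``.

    By default the stored (J-strand) orientation is used regardless of the
    feature's strand, matching genome-level reporting conventions; with
    ``strand_aware=True`` an N-strand feature is reverse-complemented
    first, which flips the skew signs.
    """
    if region is None:
        if genome.sequence is None:
            raise ValueError(f"{genome.genome_id}: no sequence available")
        return base_composition(genome.sequence)
    if isinstance(region, GeneFeature):
        if strand_aware:
            seq = extract_feature(genome, region)
        else:
            seq = extract_region(genome, region.start, region.end, "J")
    else:
        start, end = region
        seq = extract_region(genome, start, end, "J")
    return base_composition(seq)


@dataclass(frozen=True)
class CodonPositionComposition:
    """Pooled A+T percent at codon positions 1-3 over a set of CDSs."""

    at_pos1: float
    at_pos2: float
    at_pos3: float

    def rounded(self) -> tuple[float, float, float]:
        return (round(self.at_pos1, 2), round(self.at_pos2, 2), round(self.at_pos3, 2))


def codon_position_composition(cds_set: Iterable[str]) -> CodonPositionComposition:
    """A+T percent at each codon position, pooled across coding sequences.

    Sequences must already be in reading orientation; incomplete trailing
    codons are excluded.
    """
    at = [0, 0, 0]
    totals = [0, 0, 0]
    n_seqs = 0
    for cds in cds_set:
        n_seqs += 1
        s = cds.upper().replace("U", "T")
        n_codons = len(s) // 3
        for i in range(n_codons * 3):
            pos = i % 3
            totals[pos] += 1
            if s[i] in "AT":
                at[pos] += 1
    if n_seqs == 0 or totals[0] == 0:
        raise ValueError("empty CDS set")
    return CodonPositionComposition(
        *(100.0 * at[i] / totals[i] for i in range(3))
    )
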