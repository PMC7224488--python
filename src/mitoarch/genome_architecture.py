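"""Gene-junction accounting, gene-order comparison and control-region
motif scanning.

Junction accounting is linear from the first annotated feature: one
record per consecutive pair in start order, with the circular wrap-around
junction reported separately and excluded from summaries (published gene
tables account this way — the first gene starts at position 1 and the
control region ends at the last base).
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .genome_io import AnnotatedGenome

__all__ = [
    "AdjacencyRecord",
    "AdjacencySummary",
    "GeneOrder",
    "OrderComparison",
    "MotifReport",
    "adjacency_report",
    "wraparound_gap",
    "summarize_adjacencies",
    "cross_validate_gaps",
    "gene_order",
    "compare_orders",
    "scan_control_region",
]


@dataclass(frozen=True)
class AdjacencyRecord:
    """Gap between two consecutive features: positive = spacer,
    negative = overlap, 0 = abutting."""

    upstream: str
    downstream: str
    gap: int
    printed_gap: int | None = None

    @property
    def junction(self) -> str:
        return f"{self.upstream}->{self.downstream}"


def adjacency_report(genome: AnnotatedGenome) -> list[AdjacencyRecord]:
    """One record per consecutive feature pair, in genome start order."""
    feats = genome.features
    if len(feats) < 2:
        raise ValueError(f"{genome.genome_id}: need at least 2 features")
    if feats != sorted(feats, key=lambda f: (f.start, f.end)):
        warnings.warn(f"{genome.genome_id}: features unsorted, sorting")
        feats = sorted(feats, key=lambda f: (f.start, f.end))
    records = []
    for prev, nxt in zip(feats, feats[1:]):
        records.append(
            AdjacencyRecord(
                upstream=prev.gene,
                downstream=nxt.gene,
                gap=nxt.start - prev.end - 1,
                printed_gap=nxt.printed_gap,
            )
        )
    return records


def wraparound_gap(genome: AnnotatedGenome) -> AdjacencyRecord:
    """The circular junction from the last feature back to the first."""
    if genome.length is None:
        raise ValueError(f"{genome.genome_id}: genome length unknown")
    first, last = genome.features[0], genome.features[-1]
    gap = (genome.length - last.end) + (first.start - 1)
    return AdjacencyRecord(upstream=last.gene, downstream=first.gene, gap=gap)


@dataclass(frozen=True)
class AdjacencySummary:
    n_overlaps: int
    total_overlap_bp: int
    max_overlap_bp: int
    n_spacers: int
    total_spacer_bp: int
    max_spacer_bp: int
    n_abutting: int
    top_spacers: tuple[tuple[str, int], ...] = ()
    top_overlaps: tuple[tuple[str, int], ...] = ()

    @property
    def n_junctions(self) -> int:
        return self.n_overlaps + self.n_spacers + self.n_abutting


def _gap_of(rec: AdjacencyRecord, source: str) -> int:
    if source == "computed":
        return rec.gap
    if source == "printed":
        if rec.printed_gap is None:
            raise ValueError(f"no printed gap at junction {rec.junction}")
        return rec.printed_gap
    raise ValueError(f"unknown gap source {source!r}")


def summarize_adjacencies(
    records: Sequence[AdjacencyRecord],
    source: str = "computed",
    allow_empty: bool = False,
) -> AdjacencySummary:
    """Classify junction gaps into overlaps/abutments/spacers and total them.

    ``source='printed'`` uses the carried printed gap values instead of
    the coordinate-derived ones; junctions without a printed value are
    then skipped (a published table prints no value for the first gene).
    Overlap totals are magnitudes.
    """
    if source == "printed":
        records = [r for r in records if r.printed_gap is not None]
    if not records and not allow_empty:
        raise ValueError("no adjacency records")
    gaps = [(r, _gap_of(r, source)) for r in records]
    overlaps = [(r, -g) for r, g in gaps if g < 0]
    spacers = [(r, g) for r, g in gaps if g > 0]
    abutting = [r for r, g in gaps if g == 0]
    rank = lambda items: tuple(
        (r.junction, size)
        for r, size in sorted(items, key=lambda x: (-x[1], x[0].junction))
    )
    return AdjacencySummary(
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(size for _, size in overlaps),
        max_overlap_bp=max((size for _, size in overlaps), default=0),
        n_spacers=len(spacers),
        total_spacer_bp=sum(size for _, size in spacers),
        max_spacer_bp=max((size for _, size in spacers), default=0),
        n_abutting=len(abutting),
        top_spacers=rank(spacers),
        top_overlaps=rank(overlaps),
    )


def cross_validate_gaps(records: Sequence[AdjacencyRecord]) -> list[AdjacencyRecord]:
    """Junctions whose computed gap disagrees with the printed value."""
    return [
        r for r in records if r.printed_gap is not None and r.printed_gap != r.gap
    ]


# ---------------------------------------------------------------------------
# gene order
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneOrder:
    """Signed circular gene arrangement, rotated to start at trnM."""

    genome_id: str
    order: tuple[tuple[str, str], ...]  # (gene, strand)

    def genes(self) -> list[str]:
        return [g for g, _ in self.order]


def gene_order(genome: AnnotatedGenome) -> GeneOrder:
    elems = [(f.gene, f.strand) for f in genome.features]
    genes = [g for g, _ in elems]
    if "trnM" in genes:
        i = genes.index("trnM")
        elems = elems[i:] + elems[:i]
    else:
        warnings.warn(f"{genome.genome_id}: trnM absent, order left unrotated")
    return GeneOrder(genome_id=genome.genome_id, order=tuple(elems))


def _signed_adjacencies(order: Sequence[tuple[str, str]]) -> set[frozenset]:
    """Strand-aware circular adjacency signatures.

    Each gene is split into a 5' and 3' extremity on its own strand; an
    adjacency is the unordered pair of facing extremities, so inverting a
    gene changes its adjacencies even between the same neighbors.
    """
    out = set()
    n = len(order)
    for i in range(n):
        ga, sa = order[i]
        gb, sb = order[(i + 1) % n]
        left = (ga, "head" if sa == "J" else "tail")
        right = (gb, "tail" if sb == "J" else "head")
        out.add(frozenset({("L",) + left, ("R",) + right}))
    return out


@dataclass(frozen=True)
class OrderComparison:
    identical: bool
    shared_adjacencies: int
    breakpoints: int
    duplicated_in_a: tuple[str, ...]
    duplicated_in_b: tuple[str, ...]
    missing_in_a: tuple[str, ...]
    missing_in_b: tuple[str, ...]


def compare_orders(a: GeneOrder, b: GeneOrder) -> OrderComparison:
    """Duplicate-aware circular order comparison.

    Genes whose copy numbers differ between the two orders are reported
    as duplicated/missing and removed from both before adjacency
    comparison, so a tandem duplication is reported as a duplication
    rather than as breakpoints.
    """
    ca, cb = Counter(a.genes()), Counter(b.genes())
    dup_a = tuple(sorted(g for g in ca if ca[g] > cb.get(g, 0) >= 1))
    dup_b = tuple(sorted(g for g in cb if cb[g] > ca.get(g, 0) >= 1))
    miss_a = tuple(sorted(g for g in cb if ca.get(g, 0) == 0))
    miss_b = tuple(sorted(g for g in ca if cb.get(g, 0) == 0))
    unequal = {g for g in set(ca) | set(cb) if ca.get(g, 0) != cb.get(g, 0)}
    fa = [(g, s) for g, s in a.order if g not in unequal]
    fb = [(g, s) for g, s in b.order if g not in unequal]
    adj_a, adj_b = _signed_adjacencies(fa), _signed_adjacencies(fb)
    shared = len(adj_a & adj_b)
    # max over both directions keeps the count symmetric even when the two
    # adjacency sets collapse to different sizes (repeated genes)
    breakpoints = max(len(adj_a - adj_b), len(adj_b - adj_a))
    return OrderComparison(
        identical=breakpoints == 0,
        shared_adjacencies=shared,
        breakpoints=breakpoints,
        duplicated_in_a=dup_a,
        duplicated_in_b=dup_b,
        missing_in_a=miss_a,
        missing_in_b=miss_b,
    )


# ---------------------------------------------------------------------------
# control-region motif scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifReport:
    """Exact motif hits, maximal poly-T runs and tandem repeat arrays.

    Coordinates are 1-based inclusive relative to the scanned region,
    shifted by ``offset`` when a genome offset was supplied.
    """

    motif_hits: tuple[tuple[str, int, int], ...]
    polyT_runs: tuple[tuple[int, int], ...]  # (start, length)
    tandem_repeats: tuple[tuple[str, int, int, int], ...]  # (unit, copies, start, end)


def scan_control_region(
    seq: str,
    motif: str = "ATAGA",
    min_polyT: int = 10,
    min_repeat_copies: int = 3,
    repeat_units: Sequence[str] = ("AT", "AAT"),
    offset: int = 0,
) -> MotifReport:
    """Scan a non-coding region for replication/repeat signals.

    Poly-T runs and tandem arrays are maximal (not extendable by another
    T, resp. by a full unit copy, on either side).
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    hits = tuple(
        (motif, m.start() + 1 + offset, m.start() + len(motif) + offset)
        for m in re.finditer(f"(?={re.escape(motif.upper())})", s)
    )
    runs = tuple(
        (m.start() + 1 + offset, m.end() - m.start())
        for m in re.finditer("T+", s)
        if m.end() - m.start() >= min_polyT
    )
    repeats = []
    for unit in repeat_units:
        u = unit.upper()
        pattern = f"(?:{re.escape(u)}){{{min_repeat_copies},}}"
        for m in re.finditer(pattern, s):
            copies = (m.end() - m.start()) // len(u)
            repeats.append((u, copies, m.start() + 1 + offset, m.start() + copies * len(u) + offset))
    repeats.sort(key=lambda r: (r[2], r[0]))
    return MotifReport(motif_hits=hits, polyT_runs=runs, tandem_repeats=tuple(repeats))
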