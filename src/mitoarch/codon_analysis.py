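"""Codon-level analysis of mitochondrial protein-coding genes.

All translation semantics come from NCBI translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, AUA = Met, UGA = Trp; stops TAA/TAG).
Handles the incomplete stop codons (trailing T or TA completed by
polyadenylation) that are routine at mitochondrial gene boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import seq3

from .genome_io import AnnotatedGenome, GeneFeature, extract_feature

__all__ = [
    "MITO_TABLE",
    "SENSE_CODONS",
    "CANONICAL_PCG_ORDER",
    "CodonRecord",
    "CodonUsageTable",
    "RSCUTable",
    "extract_cds",
    "genome_codon_records",
    "start_stop_table",
    "count_codons",
    "amino_acid_frequencies",
    "rscu",
]

MITO_TABLE = unambiguous_dna_by_id[5]
STOP_CODONS = frozenset(MITO_TABLE.stop_codons)  # {'TAA', 'TAG'}
SENSE_CODONS = tuple(sorted(MITO_TABLE.forward_table))  # 62 codons

#: synonymous family per amino acid (full families: Leu 6, Ser 8 under table 5)
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in MITO_TABLE.forward_table.items():
    AA_FAMILIES.setdefault(_aa, ())
AA_FAMILIES = {
    aa: tuple(sorted(c for c, a in MITO_TABLE.forward_table.items() if a == aa))
    for aa in AA_FAMILIES
}

#: reporting sub-family labels for the split leucine/serine conventions
SPLIT_FAMILIES = {
    "Leu1": ("CTA", "CTC", "CTG", "CTT"),
    "Leu2": ("TTA", "TTG"),
    "Ser1": ("AGA", "AGC", "AGG", "AGT"),
    "Ser2": ("TCA", "TCC", "TCG", "TCT"),
}

#: PCG order as the genes occur along the genome from trnM
CANONICAL_PCG_ORDER = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1",
)


def codon_label(codon: str) -> str:
    """DNA codon -> RNA display form (``TTA`` -> ``UUA``)."""
    return codon.replace("T", "U")


def split_family_label(codon: str) -> str:
    """Reporting family label for a sense codon (``UUA`` style splits)."""
    for label, codons in SPLIT_FAMILIES.items():
        if codon in codons:
            return label
    return seq3(MITO_TABLE.forward_table[codon])


@dataclass(frozen=True)
class CodonRecord:
    """Start/stop classification and sense codons of one extracted CDS."""

    gene: str
    start_codon: str
    stop_codon: str
    incomplete_stop: bool
    nonstandard_stop: bool
    codons: tuple[str, ...]

    @property
    def start_stop(self) -> str:
        return f"{self.start_codon}/{self.stop_codon}"


def classify_cds(seq: str, gene: str = "?") -> CodonRecord:
    """Classify an already-oriented CDS string into a :class:`CodonRecord`.

    Trailing T (length mod 3 == 1) and TA (mod 3 == 2) are incomplete
    stops; an in-frame terminal TAA/TAG is a complete stop; anything else
    is kept but flagged nonstandard.
    """
    s = seq.upper().replace("U", "T")
    if len(s) < 6:
        raise ValueError(f"{gene}: CDS of {len(s)} nt is too short")
    remainder = len(s) % 3
    full = [s[i : i + 3] for i in range(0, len(s) - remainder, 3)]
    nonstandard = False
    if remainder == 1 and s[-1] == "T":
        stop, sense = "T", full
    elif remainder == 2 and s[-2:] == "TA":
        stop, sense = "TA", full
    elif remainder == 0 and full[-1] in STOP_CODONS:
        stop, sense = full[-1], full[:-1]
    elif remainder == 0:
        stop, sense, nonstandard = full[-1], full[:-1], True
    else:
        stop, sense, nonstandard = s[len(s) - remainder :], full, True
    return CodonRecord(
        gene=gene,
        start_codon=s[:3],
        stop_codon=stop,
        incomplete_stop=len(stop) < 3,
        nonstandard_stop=nonstandard,
        codons=tuple(sense),
    )


def extract_cds(genome: AnnotatedGenome, feature: GeneFeature) -> CodonRecord:
    """Extract a PCG in reading orientation and classify its codons."""
    if feature.ftype != "PCG":
        raise ValueError(f"{feature.gene} is not a protein-coding gene")
    return classify_cds(extract_feature(genome, feature), gene=feature.gene)


def genome_codon_records(genome: AnnotatedGenome) -> list[CodonRecord]:
    """:func:`extract_cds` applied to every PCG of ``genome``."""
    return [extract_cds(genome, f) for f in genome.pcgs]


def start_stop_table(genomes: Iterable[AnnotatedGenome]) -> pd.DataFrame:
    """Gene x genome table of ``START/STOP`` strings (NaN where absent)."""
    columns: dict[str, dict[str, str]] = {}
    for g in genomes:
        cells: dict[str, str] = {}
        for f in g.pcgs:
            if f.copy_index == 1:
                cells[f.gene] = extract_cds(g, f).start_stop
        columns[g.genome_id] = cells
    frame = pd.DataFrame(columns)
    return frame.reindex([g for g in CANONICAL_PCG_ORDER if g in frame.index])


@dataclass(frozen=True)
class CodonUsageTable:
    """Sense-codon counts pooled over a set of CDS records."""

    counts: Mapping[str, int]
    n_ambiguous: int = 0
    n_internal_stops: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonUsageTable(
            dict(merged),
            self.n_ambiguous + other.n_ambiguous,
            self.n_internal_stops + other.n_internal_stops,
        )


def count_codons(records: Iterable[CodonRecord]) -> CodonUsageTable:
    """Pool sense-codon counts; codons with ambiguity codes are excluded
    and tallied in ``n_ambiguous``, in-frame stop triplets (possible in
    nonstandard records) in ``n_internal_stops``."""
    counts: Counter[str] = Counter()
    n_amb = n_stop = 0
    n_records = 0
    for rec in records:
        n_records += 1
        for codon in rec.codons:
            if codon in STOP_CODONS:
                n_stop += 1
            elif codon in MITO_TABLE.forward_table:
                counts[codon] += 1
            else:
                n_amb += 1
    if n_records == 0:
        raise ValueError("no codon records")
    return CodonUsageTable(dict(counts), n_amb, n_stop)


def amino_acid_frequencies(usage: CodonUsageTable) -> dict[str, float]:
    """Percent of total sense codons per amino acid (3-letter names),
    with the pooled Leu/Ser entries accompanied by split Leu1/Leu2 and
    Ser1/Ser2 entries."""
    total = usage.total_codons
    if total == 0:
        raise ValueError("empty usage table")
    freqs: dict[str, float] = {}
    for aa, family in AA_FAMILIES.items():
        n = sum(usage.counts.get(c, 0) for c in family)
        freqs[seq3(aa)] = 100.0 * n / total
    for label, family in SPLIT_FAMILIES.items():
        n = sum(usage.counts.get(c, 0) for c in family)
        freqs[label] = 100.0 * n / total
    return freqs


@dataclass(frozen=True)
class RSCUTable:
    """Relative synonymous codon usage over full synonymous families."""

    rscu: Mapping[str, float | None]

    def top(self, n: int = 4) -> list[tuple[str, float]]:
        observed = [(c, v) for c, v in self.rscu.items() if v is not None]
        return sorted(observed, key=lambda cv: (-cv[1], cv[0]))[:n]

    def as_frame(self, usage: CodonUsageTable | None = None) -> pd.DataFrame:
        rows = []
        for codon in SENSE_CODONS:
            rows.append(
                {
                    "amino_acid": split_family_label(codon),
                    "codon": codon_label(codon),
                    "count": None if usage is None else usage.counts.get(codon, 0),
                    "rscu": self.rscu[codon],
                }
            )
        return pd.DataFrame(rows).sort_values(["amino_acid", "codon"]).reset_index(drop=True)


def rscu(usage: CodonUsageTable) -> RSCUTable:
    """RSCU(c) = count(c) / mean count over c's synonymous family.

    Families with zero observed codons yield ``None`` entries; family sums
    equal the family degeneracy whenever the family is observed.
    """
    values: dict[str, float | None] = {}
    for family in AA_FAMILIES.values():
        family_total = sum(usage.counts.get(c, 0) for c in family)
        if family_total == 0:
            for c in family:
                values[c] = None
            continue
        mean = family_total / len(family)
        for c in family:
            values[c] = usage.counts.get(c, 0) / mean
    return RSCUTable(values)
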