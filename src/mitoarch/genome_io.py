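"""Reading and writing annotated mitogenomes.

Coordinate convention used throughout the package:

* positions are 1-based and fully inclusive (``length = end - start + 1``);
* the gap between consecutive features is ``next.start - prev.end - 1``
  (positive = intergenic spacer, negative = overlap, 0 = abutting);
* strands are ``J`` (majority/forward, ``+``/``F``) and ``N`` (minority,
  ``-``/``R``); no feature wraps around the origin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_complement

from .vocab import (
    CONTROL_REGION,
    GENE_TYPE,
    UnknownGeneError,
    normalize_gene,
    try_normalize_gene,
)

__all__ = [
    "GeneFeature",
    "AnnotatedGenome",
    "GenomeIOError",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "extract_region",
    "reverse_complement",
]

_STRAND_ALIASES = {
    "J": "J", "N": "N", "F": "J", "R": "N", "+": "J", "-": "N",
}

_COMPLEMENT = {**{k.upper(): v.upper() for k, v in ambiguous_dna_complement.items()}}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)


class GenomeIOError(ValueError):
    """Malformed input file or invalid coordinates."""


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement of a DNA string.

    Raises :class:`GenomeIOError` on characters outside the IUPAC DNA
    alphabet.  Case is not preserved; output is upper-case.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(_COMPLEMENT)
    if bad:
        raise GenomeIOError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s.translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated feature on a circular mitogenome."""

    gene: str
    ftype: str
    strand: str
    start: int
    end: int
    copy_index: int = 1
    printed_gap: int | None = None

    def __post_init__(self) -> None:
        if self.ftype not in ("PCG", "tRNA", "rRNA", "control_region"):
            raise GenomeIOError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("J", "N"):
            raise GenomeIOError(f"strand must be J or N, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise GenomeIOError(
                f"invalid coordinates for {self.gene}: {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene, self.copy_index)


@dataclass
class AnnotatedGenome:
    """A (possibly sequence-less) annotated circular mitogenome."""

    genome_id: str
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    length: int | None = None
    taxon: str = ""
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise GenomeIOError(
                    f"{self.genome_id}: length field {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        elif self.length is None and self.features:
            self.length = max(f.end for f in self.features)
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: set[tuple[str, int]] = set()
        for f in self.features:
            if f.key in seen:
                raise GenomeIOError(
                    f"{self.genome_id}: duplicate feature {f.gene} "
                    f"(copy {f.copy_index})"
                )
            seen.add(f.key)
            if self.length is not None and f.end > self.length:
                raise GenomeIOError(
                    f"{self.genome_id}: feature {f.gene} ends at {f.end} "
                    f"beyond genome length {self.length}"
                )

    def get(self, gene: str, copy_index: int = 1) -> GeneFeature:
        for f in self.features:
            if f.gene == gene and f.copy_index == copy_index:
                return f
        raise KeyError(f"{self.genome_id}: no feature {gene} (copy {copy_index})")

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.features_of_type("PCG")

    def to_json(self) -> str:
        doc = {
            "genome_id": self.genome_id,
            "taxon": self.taxon,
            "length": self.length,
            "circular": self.circular,
            "sequence": self.sequence,
            "features": [
                {
                    "gene": f.gene,
                    "ftype": f.ftype,
                    "strand": f.strand,
                    "start": f.start,
                    "end": f.end,
                    "copy_index": f.copy_index,
                    "printed_gap": f.printed_gap,
                }
                for f in self.features
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnnotatedGenome":
        doc = json.loads(text)
        feats = [GeneFeature(**f) for f in doc["features"]]
        return cls(
            genome_id=doc["genome_id"],
            taxon=doc.get("taxon", ""),
            length=doc.get("length"),
            circular=doc.get("circular", True),
            sequence=doc.get("sequence"),
            features=feats,
        )


def extract_region(genome: AnnotatedGenome, start: int, end: int, strand: str = "J") -> str:
    """Inclusive 1-based substring, reverse-complemented when strand is N."""
    if genome.sequence is None:
        raise GenomeIOError(f"{genome.genome_id}: no sequence available")
    if not (1 <= start <= end <= len(genome.sequence)):
        raise GenomeIOError(
            f"{genome.genome_id}: region {start}..{end} out of range "
            f"1..{len(genome.sequence)}"
        )
    sub = genome.sequence[start - 1 : end]
    strand = _STRAND_ALIASES.get(strand.upper(), strand)
    if strand == "N":
        return reverse_complement(sub)
    return sub


def extract_feature(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Feature sequence in reading orientation (5'->3' of its own strand)."""
    return extract_region(genome, feature.start, feature.end, feature.strand)


# ---------------------------------------------------------------------------
# gene tables (TSV)
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["genome_id", "gene", "type", "strand", "start", "end", "printed_gap"]


def _parse_table_row(row: dict[str, str], lineno: int, permissive: bool) -> tuple[str, GeneFeature]:
    raw_gene = row["gene"].strip()
    gene = try_normalize_gene(raw_gene)
    if gene is None:
        if not permissive:
            raise UnknownGeneError(f"line {lineno}: unknown gene symbol {raw_gene!r}")
        warnings.warn(f"line {lineno}: keeping unresolved gene name {raw_gene!r}")
        gene = raw_gene
        ftype = row.get("type", "tRNA").strip() or "tRNA"
    else:
        ftype = GENE_TYPE[gene]
        declared = (row.get("type") or "").strip()
        if declared and declared != ftype:
            warnings.warn(
                f"line {lineno}: declared type {declared!r} for {gene} "
                f"overridden by vocabulary type {ftype!r}"
            )
    try:
        start, end = int(row["start"]), int(row["end"])
    except (TypeError, ValueError):
        raise GenomeIOError(f"line {lineno}: non-integer coordinates") from None
    if start > end:
        raise GenomeIOError(f"line {lineno}: start {start} > end {end}")
    strand_raw = row["strand"].strip().upper()
    if strand_raw not in _STRAND_ALIASES:
        raise GenomeIOError(f"line {lineno}: unknown strand {row['strand']!r}")
    gap_raw = (row.get("printed_gap") or "").strip()
    printed_gap = int(gap_raw) if gap_raw not in ("", "-", ".") else None
    copy_raw = (row.get("copy_index") or "").strip()
    copy_index = int(copy_raw) if copy_raw else 1
    feat = GeneFeature(
        gene=gene,
        ftype=ftype,
        strand=_STRAND_ALIASES[strand_raw],
        start=start,
        end=end,
        copy_index=copy_index,
        printed_gap=printed_gap,
    )
    return row["genome_id"].strip(), feat


def read_gene_table(path: str | Path, permissive: bool = False) -> list[AnnotatedGenome]:
    """Read a tab-separated gene table into one genome per ``genome_id``.

    Expected header: ``genome_id gene type strand start end`` with optional
    ``printed_gap`` and ``copy_index`` columns; ``#`` lines are comments.
    Duplicate gene symbols within a genome are auto-assigned increasing
    copy indices in file order when no explicit ``copy_index`` is given.
    """
    path = Path(path)
    genomes: dict[str, list[GeneFeature]] = {}
    with path.open("r", encoding="utf-8") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = {"genome_id", "gene", "strand", "start", "end"} - set(header)
                if missing:
                    raise GenomeIOError(f"{path}: missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, cells))
            gid, feat = _parse_table_row(row, lineno, permissive)
            bucket = genomes.setdefault(gid, [])
            if "copy_index" not in header:
                n_prev = sum(1 for f in bucket if f.gene == feat.gene)
                if n_prev:
                    feat = replace(feat, copy_index=n_prev + 1)
            bucket.append(feat)
    if header is None:
        raise GenomeIOError(f"{path}: empty file")
    if not genomes:
        raise GenomeIOError(f"{path}: no records")
    return [AnnotatedGenome(genome_id=gid, features=feats) for gid, feats in genomes.items()]


def write_gene_table(genomes: Iterable[AnnotatedGenome], path: str | Path) -> None:
    """Write genomes to the TSV layout accepted by :func:`read_gene_table`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TABLE_COLUMNS + ["copy_index"]) + "\n")
        for g in genomes:
            for f in g.features:
                gap = "" if f.printed_gap is None else str(f.printed_gap)
                fh.write(
                    "\t".join(
                        [
                            g.genome_id, f.gene, f.ftype, f.strand,
                            str(f.start), str(f.end), gap, str(f.copy_index),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All records of a FASTA file as ``(id, upper-case sequence)`` pairs."""
    records = [
        (rec.id, str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise GenomeIOError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_GENBANK_FTYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                   "D-loop": "control_region", "misc_feature": "control_region"}


def _genbank_feature_name(feat) -> str | None:
    for qual in ("gene", "product", "note"):
        for value in feat.qualifiers.get(qual, []):
            got = try_normalize_gene(value)
            if got is not None:
                return got
    return None


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Read a GenBank flat file into an :class:`AnnotatedGenome`.

    CDS/tRNA/rRNA/D-loop features are mapped onto the controlled
    vocabulary; unresolvable names are kept verbatim with a warning.
    """
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None:
        raise GenomeIOError(f"{path}: no records")
    feats: list[GeneFeature] = []
    counts: dict[str, int] = {}
    for feat in rec.features:
        if feat.type not in _GENBANK_FTYPES:
            continue
        name = _genbank_feature_name(feat)
        ftype = _GENBANK_FTYPES[feat.type]
        if name is None:
            raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("product") or ["?"])[0]
            if feat.type in ("D-loop", "misc_feature"):
                name = CONTROL_REGION
            else:
                warnings.warn(f"{path}: unresolved gene name {raw!r}, kept verbatim")
                name = raw
        else:
            ftype = GENE_TYPE.get(name, ftype)
        start = int(feat.location.start) + 1  # biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "N" if feat.location.strand == -1 else "J"
        counts[name] = counts.get(name, 0) + 1
        feats.append(
            GeneFeature(gene=name, ftype=ftype, strand=strand,
                        start=start, end=end, copy_index=counts[name])
        )
    return AnnotatedGenome(
        genome_id=rec.id or rec.name,
        taxon=rec.annotations.get("organism", ""),
        sequence=str(rec.seq),
        features=feats,
        circular=rec.annotations.get("topology", "circular") == "circular",
    )


def attach_sequence(genome: AnnotatedGenome, sequence: str) -> AnnotatedGenome:
    """Return a copy of ``genome`` carrying ``sequence``."""
    return AnnotatedGenome(
        genome_id=genome.genome_id,
        taxon=genome.taxon,
        sequence=sequence,
        features=list(genome.features),
        circular=genome.circular,
    )
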