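"""Distance-based phylogeny utilities: supermatrix construction,
Kimura 2-parameter distances, neighbor joining and Robinson–Foulds
topology comparison.

This is deliberately lightweight — a falsifiable sanity layer over
concatenated PCG alignments, not a replacement for model-based ML/BI
inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .codon_analysis import CANONICAL_PCG_ORDER

__all__ = [
    "Supermatrix",
    "DistanceMatrix",
    "build_supermatrix",
    "k2p_distance",
    "distance_matrix",
    "nj_tree",
    "rf_distance",
]

_GAP_CHARS = frozenset("-?")
_PURINES = frozenset("AG")


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated per-gene alignment with recorded column partitions."""

    taxa: tuple[str, ...]
    sequences: Mapping[str, str]
    partitions: tuple[tuple[str, int, int], ...]  # (gene, first_col, last_col) 1-based

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.taxa else 0

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)} {self.n_columns}"]
        for t in self.taxa:
            lines.append(f"{t}  {self.sequences[t]}")
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_columns};",
            "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "  MATRIX",
        ]
        for t in self.taxa:
            lines.append(f"    {t}  {self.sequences[t]}")
        lines += ["  ;", "END;", "", "BEGIN SETS;"]
        for gene, a, b in self.partitions:
            lines.append(f"  CHARSET {gene} = {a}-{b};")
        lines += ["END;", ""]
        return "\n".join(lines)


def build_supermatrix(
    gene_blocks: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str] | None = None,
    drop_gapped: bool = False,
) -> Supermatrix:
    """Concatenate pre-aligned per-gene blocks into one matrix.

    Genes are concatenated in the canonical genome order (from trnM);
    genes outside that list follow in input order.  Every gene must carry
    every taxon exactly once with equal row lengths.  ``drop_gapped``
    removes all columns containing a gap character (complete deletion).
    """
    if not gene_blocks:
        raise ValueError("no gene blocks")
    if gene_order is None:
        canon = [g for g in CANONICAL_PCG_ORDER if g in gene_blocks]
        gene_order = canon + [g for g in gene_blocks if g not in canon]
    taxa: tuple[str, ...] | None = None
    for gene in gene_order:
        block = gene_blocks[gene]
        if taxa is None:
            taxa = tuple(block)
        missing = set(taxa) ^ set(block)
        if missing:
            raise ValueError(f"gene {gene}: taxon set mismatch ({sorted(missing)})")
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise ValueError(f"gene {gene}: unequal row lengths {sorted(widths)}")
    assert taxa is not None
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    col = 1
    for gene in gene_order:
        block = gene_blocks[gene]
        rows = {t: block[t].upper() for t in taxa}
        if drop_gapped:
            width = len(next(iter(rows.values())))
            keep = [
                j for j in range(width)
                if not any(rows[t][j] in _GAP_CHARS for t in taxa)
            ]
            rows = {t: "".join(rows[t][j] for j in keep) for t in taxa}
        width = len(next(iter(rows.values())))
        if width:
            parts.append((gene, col, col + width - 1))
            col += width
        for t in taxa:
            chunks[t].append(rows[t])
    return Supermatrix(
        taxa=taxa,
        sequences={t: "".join(chunks[t]) for t in taxa},
        partitions=tuple(parts),
    )


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance over ungapped, unambiguous site pairs.

    Returns ``inf`` (with a warning) when the correction saturates.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    a, b = seq_a.upper(), seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn("K2P distance saturated; reporting inf")
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def distance_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise K2P distances over an aligned sequence mapping."""
    taxa = tuple(sequences)
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = k2p_distance(sequences[taxa[i]], sequences[taxa[j]])
    return DistanceMatrix(taxa=taxa, matrix=m)


def _clamp(x: float) -> float:
    if x < 0:
        warnings.warn(f"negative branch length {x:.6g} clamped to 0")
        return 0.0
    return x


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Ties in the Q criterion are broken by the lowest (i, j) index pair so
    runs are reproducible; negative branch lengths are clamped to zero.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.all(np.isfinite(dist.matrix)):
        raise ValueError("non-finite distances")
    d = dist.matrix.copy()
    nodes = [f"{t}" for t in dist.taxa]  # newick fragments
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        li = _clamp(0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2)))
        lj = _clamp(0.5 * d[i, j] + (sums[j] - sums[i]) / (2 * (r - 2)))
        new = len(nodes)
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new]
    i, j, k = active
    li = _clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = _clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = _clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    return f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g},{nodes[k]}:{lk:.10g});"


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson–Foulds symmetric difference between two unrooted trees."""
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=ns)
    labels1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    labels2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError(f"leaf sets differ: {sorted(labels1 ^ labels2)}")
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
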