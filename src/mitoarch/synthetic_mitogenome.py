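"""Seeded generators for annotated mitogenomes and tree-evolved
alignments, so every analysis stage can be tested without downloads.

A generated genome realizes a 37-gene circular arrangement (insect gene
order starting at trnM), a per-junction gap/overlap plan, AT-biased
composition, chosen start/stop codons per protein-coding gene, and a
control region carrying a plantable motif, poly-T stretch and short
tandem repeats.  All randomness flows through one ``numpy`` generator
seeded from the spec; truth metadata for every planted quantity is
returned alongside the genome.

Overlap semantics: the downstream gene's sequence wins in overlapped
bases, so an upstream gene's tail is whatever the overlap imposes — its
planted stop codon may be rendered incomplete or nonstandard, and the
truth metadata records the *realized* classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import dendropy
import numpy as np

from .genome_io import AnnotatedGenome, GeneFeature, reverse_complement
from .vocab import GENE_TYPE

__all__ = [
    "CRPlan",
    "SimSpec",
    "GenerationResult",
    "default_spec",
    "generate_mitogenome",
    "evolve_sequences",
]

#: 37-gene arrangement starting at trnM with the usual lepidopteran
#: strand pattern, plus the control region; lengths are realistic defaults.
DEFAULT_GENE_ORDER: tuple[tuple[str, str, int], ...] = (
    ("trnM", "J", 67), ("trnI", "J", 64), ("trnQ", "N", 69),
    ("ND2", "J", 1035), ("trnW", "J", 70), ("trnC", "N", 67),
    ("trnY", "N", 71), ("COI", "J", 1503), ("trnL2", "J", 67),
    ("COII", "J", 684), ("trnK", "J", 71), ("trnD", "J", 67),
    ("ATP8", "J", 162), ("ATP6", "J", 675), ("COIII", "J", 789),
    ("trnG", "J", 66), ("ND3", "J", 354), ("trnA", "J", 68),
    ("trnR", "J", 65), ("trnN", "J", 67), ("trnS1", "J", 66),
    ("trnE", "J", 69), ("trnF", "N", 67), ("ND5", "N", 1686),
    ("trnH", "N", 64), ("ND4", "N", 1338), ("ND4L", "N", 267),
    ("trnT", "J", 65), ("trnP", "N", 65), ("ND6", "J", 522),
    ("CytB", "J", 1146), ("trnS2", "J", 66), ("ND1", "N", 930),
    ("trnL1", "N", 68), ("rrnL", "N", 1365), ("trnV", "N", 68),
    ("rrnS", "N", 776), ("CR", "J", 319),
)

#: per-junction gap plan matching the default order (37 linear junctions)
DEFAULT_JUNCTION_PLAN: tuple[int, ...] = (
    1, -3, 31, -2, -8, 1, 60, -5, 0, 1, 1, 0, -4, 16, 2, 0, -2, 9, 4,
    20, 0, 8, 4, 57, 1, 31, 31, 0, 17, 8, 3, -1, 25, 40, -1, 0, 0,
)

DEFAULT_START_CODONS: dict[str, str] = {
    "ND2": "ATA", "COI": "CGA", "COII": "ATA", "ATP8": "ATT",
    "ATP6": "ATG", "COIII": "ATG", "ND3": "ATT", "ND5": "ATA",
    "ND4": "ATG", "ND4L": "ATG", "ND6": "ATA", "CytB": "ATG", "ND1": "ATG",
}

DEFAULT_STOP_CODONS: dict[str, str] = {
    "ND2": "TAA", "COI": "TAA", "COII": "TAA", "ATP8": "TAA",
    "ATP6": "TAA", "COIII": "TAA", "ND3": "TAG", "ND5": "TAA",
    "ND4": "TAA", "ND4L": "TAA", "ND6": "TAA", "CytB": "TAA", "ND1": "TAA",
}

_STOPS = ("TAA", "TAG")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class CRPlan:
    """Recipe for the control-region sequence."""

    motif: str = "ATAGA"
    polyT_length: int = 14
    tandem_repeats: tuple[tuple[str, int], ...] = (("AT", 6), ("AAT", 4))
    filler_at: float = 0.92

    def min_length(self) -> int:
        planted = len(self.motif) + self.polyT_length + sum(
            len(u) * n for u, n in self.tandem_repeats
        )
        # two guard bases around every planted element
        return planted + 2 * (2 + len(self.tandem_repeats))


@dataclass(frozen=True)
class SimSpec:
    gene_order: tuple[tuple[str, str, int], ...] = DEFAULT_GENE_ORDER
    junction_plan: tuple[int, ...] = DEFAULT_JUNCTION_PLAN
    at_content_target: float = 0.80
    codon_bias: Mapping[str, float] | None = None
    start_codons: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_START_CODONS))
    stop_codons: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STOP_CODONS))
    cr_plan: CRPlan = field(default_factory=CRPlan)
    seed: int = 0
    genome_id: str = "SIM"

    def validate(self) -> None:
        if not 0.0 < self.at_content_target < 1.0:
            raise ValueError("at_content_target must lie in (0, 1)")
        if len(self.junction_plan) != len(self.gene_order) - 1:
            raise ValueError(
                f"junction plan has {len(self.junction_plan)} entries for "
                f"{len(self.gene_order)} genes (need n-1)"
            )
        for gene, strand, length in self.gene_order:
            if length <= 0:
                raise ValueError(f"{gene}: non-positive length")
            if strand not in ("J", "N"):
                raise ValueError(f"{gene}: strand must be J or N")
        for i, gap in enumerate(self.junction_plan):
            up_len = self.gene_order[i][2]
            down_len = self.gene_order[i + 1][2]
            if gap < 0 and -gap >= min(up_len, down_len):
                raise ValueError(
                    f"overlap {-gap} at junction {i} exceeds the shorter "
                    f"neighbor ({min(up_len, down_len)} bp)"
                )
        for gene, strand, length in self.gene_order:
            if GENE_TYPE.get(gene) == "PCG":
                stop = self.stop_codons.get(gene, "TAA")
                body = length - len(stop)
                if body % 3 != 0 or body < 6:
                    raise ValueError(
                        f"{gene}: length {length} incompatible with stop "
                        f"{stop!r} (body must be whole codons, >= 6 nt)"
                    )
        cr = [l for g, _, l in self.gene_order if g == "CR"]
        if cr and cr[0] < self.cr_plan.min_length():
            raise ValueError(
                f"control region of {cr[0]} bp too short for its plan "
                f"(needs >= {self.cr_plan.min_length()})"
            )


def default_spec(**overrides) -> SimSpec:
    return replace(SimSpec(), **overrides)


def with_duplicate_trnr(spec: SimSpec) -> SimSpec:
    """Variant with a second trnR copy inserted after trnS1 (the
    *Kunugia*-style duplication), for duplicate-detection tests."""
    order = list(spec.gene_order)
    plan = list(spec.junction_plan)
    i = [g for g, _, _ in order].index("trnS1")
    order.insert(i + 1, ("trnR", "J", 64))
    plan.insert(i + 1, 5)  # gap trnS1 -> trnR copy
    return replace(spec, gene_order=tuple(order), junction_plan=tuple(plan))


def _iid_bases(rng: np.random.Generator, n: int, at: float) -> str:
    probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return "".join(rng.choice(("A", "T", "G", "C"), size=n, p=probs)) if n else ""


def _default_codon_bias(at: float) -> dict[str, float]:
    # product-form weights: per-base odds chosen so sense codons land near
    # the genome-wide A+T target
    r = at / (1.0 - at)
    return {
        c: r ** sum(1 for b in c if b in "AT") for c in _SENSE_CODONS
    }


def _sample_codons(rng: np.random.Generator, n: int, bias: Mapping[str, float]) -> list[str]:
    codons = [c for c in _SENSE_CODONS if bias.get(c, 0) > 0]
    weights = np.array([bias[c] for c in codons], dtype=float)
    weights /= weights.sum()
    return list(rng.choice(codons, size=n, p=weights)) if n else []


def _build_cr(rng: np.random.Generator, plan: CRPlan, length: int) -> tuple[str, dict]:
    """Control region: filler interleaved with guarded planted elements.

    Guard bases (C/G) flank each element so planted runs and tandem
    arrays stay maximal and recoverable.  Filler avoids long T runs.
    """
    if plan.motif and not plan.motif.endswith("T"):
        # the classic layout: motif immediately followed by the poly-T run
        elements: list[tuple[str, str]] = [
            ("motif+polyT", plan.motif + "T" * plan.polyT_length)
        ]
    else:
        elements = [
            ("motif", plan.motif),
            ("polyT", "T" * plan.polyT_length),
        ]
    for unit, copies in plan.tandem_repeats:
        elements.append((f"repeat:{unit}", unit * copies))
    guarded = [("C" + seq + "G", kind, seq) for kind, seq in elements]
    fixed = sum(len(g) for g, _, _ in guarded)
    n_fill = length - fixed
    if n_fill < 0:
        raise ValueError("control region too short for its plan")
    cuts = sorted(int(c) for c in rng.integers(0, n_fill + 1, size=len(guarded)))
    fillers = []
    prev = 0
    for c in list(cuts) + [n_fill]:
        fillers.append(c - prev)
        prev = c
    def filler(n: int) -> str:
        # cap T runs at 3 so planted poly-T stays unique and maximal
        out = []
        run = 0
        for b in _iid_bases(rng, n, plan.filler_at):
            if b == "T":
                run += 1
                if run > 3:
                    b = "A"
                    run = 0
            else:
                run = 0
            out.append(b)
        return "".join(out)

    parts = [filler(fillers[0])]
    truth: dict = {"motif": None, "polyT": None, "repeats": []}
    pos = len(parts[0])
    for (g, kind, seq), nfill in zip(guarded, fillers[1:]):
        start = pos + 2  # 1-based start of the payload (after the C guard)
        if kind == "motif+polyT":
            motif_len = len(seq) - plan.polyT_length
            truth["motif"] = (seq[:motif_len], start, start + motif_len - 1)
            truth["polyT"] = (start + motif_len, plan.polyT_length)
        elif kind == "motif":
            truth["motif"] = (seq, start, start + len(seq) - 1)
        elif kind == "polyT":
            truth["polyT"] = (start, len(seq))
        else:
            unit = kind.split(":", 1)[1]
            truth["repeats"].append(
                (unit, len(seq) // len(unit), start, start + len(seq) - 1)
            )
        parts.append(g)
        parts.append(filler(nfill))
        pos += len(g) + nfill
    cr = "".join(parts)
    assert len(cr) == length
    return cr, truth


def _classify_tail(seq: str) -> tuple[str, bool, bool]:
    """(stop, incomplete, nonstandard) of an oriented CDS — generator-side
    bookkeeping, intentionally kept local to this module."""
    r = len(seq) % 3
    if r == 1 and seq.endswith("T"):
        return "T", True, False
    if r == 2 and seq.endswith("TA"):
        return "TA", True, False
    last = seq[len(seq) - r - 3 : len(seq) - r] if len(seq) >= r + 3 else ""
    if r == 0 and last in _STOPS:
        return last, False, False
    if r == 0:
        return last, False, True
    return seq[len(seq) - r :], True, True


@dataclass(frozen=True)
class GenerationResult:
    genome: AnnotatedGenome
    truth: dict


def generate_mitogenome(spec: SimSpec) -> GenerationResult:
    """Render ``spec`` into a sequence-bearing :class:`AnnotatedGenome`.

    Deterministic given ``spec.seed``.  The returned truth metadata holds
    the planned gaps, the realized start/stop codon of every PCG, and the
    genome-coordinate positions of all planted control-region elements.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bias = spec.codon_bias or _default_codon_bias(spec.at_content_target)

    # coordinates
    coords: list[tuple[int, int]] = []
    pos = 1
    for i, (gene, strand, length) in enumerate(spec.gene_order):
        start = pos
        end = start + length - 1
        coords.append((start, end))
        if i < len(spec.junction_plan):
            pos = end + 1 + spec.junction_plan[i]
    genome_length = max(e for _, e in coords)

    buf = np.full(genome_length, b"-", dtype="S1")
    cr_truth: dict | None = None
    cr_offset = 0
    for (gene, strand, length), (start, end) in zip(spec.gene_order, coords):
        ftype = GENE_TYPE.get(gene, "tRNA")
        if ftype == "PCG":
            stop = spec.stop_codons.get(gene, "TAA")
            start_codon = spec.start_codons.get(gene, "ATG")
            n_body = (length - len(stop)) // 3 - 1  # codons after the start
            oriented = start_codon + "".join(_sample_codons(rng, n_body, bias)) + stop
        elif ftype == "control_region":
            oriented, cr_truth = _build_cr(rng, spec.cr_plan, length)
            cr_offset = start - 1
        else:
            oriented = _iid_bases(rng, length, spec.at_content_target)
        rendered = reverse_complement(oriented) if strand == "N" else oriented
        buf[start - 1 : end] = np.frombuffer(rendered.encode(), dtype="S1")

    # non-feature positions (spacers) get i.i.d. background
    gapmask = buf == b"-"
    n_gap = int(gapmask.sum())
    if n_gap:
        buf[gapmask] = np.frombuffer(
            _iid_bases(rng, n_gap, spec.at_content_target).encode(), dtype="S1"
        )
    sequence = buf.tobytes().decode()

    features = []
    counts: dict[str, int] = {}
    for i, ((gene, strand, length), (start, end)) in enumerate(zip(spec.gene_order, coords)):
        counts[gene] = counts.get(gene, 0) + 1
        features.append(
            GeneFeature(
                gene=gene,
                ftype=GENE_TYPE.get(gene, "tRNA"),
                strand=strand,
                start=start,
                end=end,
                copy_index=counts[gene],
                printed_gap=spec.junction_plan[i - 1] if i > 0 else None,
            )
        )
    genome = AnnotatedGenome(
        genome_id=spec.genome_id, sequence=sequence, features=features
    )

    # realized start/stop per PCG (tails may have been overwritten by a
    # downstream overlap; record what is actually in the sequence)
    startstop: dict[str, dict] = {}
    for f in features:
        if f.ftype != "PCG":
            continue
        sub = sequence[f.start - 1 : f.end]
        cds = reverse_complement(sub) if f.strand == "N" else sub
        stop, incomplete, nonstandard = _classify_tail(cds)
        startstop[f.gene] = {
            "start_codon": cds[:3],
            "stop_codon": stop,
            "incomplete_stop": incomplete,
            "nonstandard_stop": nonstandard,
        }

    truth = {
        "genome_length": genome_length,
        "junction_plan": list(spec.junction_plan),
        "start_stop": startstop,
        "at_content_target": spec.at_content_target,
        "control_region": None,
    }
    if cr_truth is not None:
        truth["control_region"] = {
            "offset": cr_offset,
            "motif": cr_truth["motif"],
            "polyT": cr_truth["polyT"],
            "repeats": cr_truth["repeats"],
        }
    return GenerationResult(genome=genome, truth=truth)


# ---------------------------------------------------------------------------
# sequence evolution along a tree
# ---------------------------------------------------------------------------

_BASES = np.array(["A", "C", "G", "T"])
_IDX = {b: i for i, b in enumerate(_BASES)}


def _k2p_matrix(t: float, kappa: float) -> np.ndarray:
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    p_same = 1.0 - p_ts - 2.0 * p_tv
    # base order A C G T; transitions A<->G and C<->T
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[0, 2] = P[2, 0] = p_ts
    P[1, 3] = P[3, 1] = p_ts
    return P


def _f81_matrix(t: float, pi: np.ndarray) -> np.ndarray:
    beta = 1.0 / (1.0 - float(np.sum(pi**2)))
    e = math.exp(-beta * t)
    P = np.tile(pi, (4, 1)) * (1.0 - e)
    P += np.eye(4) * e
    return P


def evolve_sequences(
    tree: str | dendropy.Tree,
    root_length: int | None = None,
    root_seq: str | None = None,
    model: str = "k2p",
    kappa: float = 2.0,
    at_content: float = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """Simulate i.i.d.-per-site substitution along ``tree``.

    ``model`` is ``"k2p"`` (Kimura 2-parameter with transition/transversion
    rate ratio ``kappa``) or ``"jc-at"`` (equal-rate model with A/T-biased
    equilibrium frequencies — an F81 parameterization that reduces to
    Jukes–Cantor at ``at_content=0.5``).  Branch lengths are expected
    substitutions per site.  Returns leaf label -> sequence.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if (root_seq is None) == (root_length is None):
        raise ValueError("provide exactly one of root_seq / root_length")
    if model == "k2p":
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        pi = np.full(4, 0.25)
        pmat = lambda t: _k2p_matrix(t, kappa)
    elif model == "jc-at":
        if not 0.0 < at_content < 1.0:
            raise ValueError("at_content must lie in (0, 1)")
        pi = np.array([at_content / 2, (1 - at_content) / 2,
                       (1 - at_content) / 2, at_content / 2])
        pmat = lambda t: _f81_matrix(t, pi)
    else:
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(seed)
    if root_seq is not None:
        root = np.array([_IDX[b] for b in root_seq.upper()], dtype=np.int64)
    else:
        root = rng.choice(4, size=root_length, p=pi)

    states: dict[int, np.ndarray] = {id(tree.seed_node): root}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_state = states[id(node)]
        else:
            t = node.edge.length or 0.0
            if t < 0:
                raise ValueError("negative branch length")
            parent_state = states[id(node.parent_node)]
            if t == 0:
                child = parent_state.copy()
            else:
                P = pmat(t)
                child = np.empty_like(parent_state)
                for b in range(4):
                    mask = parent_state == b
                    k = int(mask.sum())
                    if k:
                        child[mask] = rng.choice(4, size=k, p=P[b])
            states[id(node)] = child
            parent_state = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else "?"
            out[label] = "".join(_BASES[parent_state])
    return out
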