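"""Controlled gene vocabulary and name normalization.

Canonical symbols: 13 protein-coding genes, 22 tRNAs (``trnX``, with the
two leucine/serine isoacceptors split as trnL1/trnL2 and trnS1/trnS2),
the two rRNAs (``rrnL``, ``rrnS``) and the control region (``CR``).
Annotation sources use wildly heterogeneous synonyms ("COX1", "NAD4L",
"l-rRNA", "tRNA-Leu(UUR)" ...); a shipped alias table maps them onto the
canonical set.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources

PCG_GENES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CytB",
)

TRNA_GENES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNA_GENES = ("rrnL", "rrnS")

CONTROL_REGION = "CR"

ALL_GENES = PCG_GENES + TRNA_GENES + RRNA_GENES + (CONTROL_REGION,)

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control_region")

#: canonical symbol -> feature type
GENE_TYPE = {g: "PCG" for g in PCG_GENES}
GENE_TYPE.update({g: "tRNA" for g in TRNA_GENES})
GENE_TYPE.update({g: "rRNA" for g in RRNA_GENES})
GENE_TYPE[CONTROL_REGION] = "control_region"


def _squash(name: str) -> str:
    """Normalization key: lower-case, strip everything but letters/digits."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


@lru_cache(maxsize=1)
def _alias_map() -> dict[str, str]:
    amap: dict[str, str] = {_squash(g): g for g in ALL_GENES}
    path = resources.files("mitoarch") / "data" / "gene_aliases.tsv"
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.reader(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")),
            delimiter="\t",
        ):
            alias, canonical = row[0], row[1]
            if canonical not in GENE_TYPE:
                raise ValueError(f"alias table maps to unknown symbol {canonical!r}")
            amap[_squash(alias)] = canonical
    return amap


class UnknownGeneError(KeyError):
    """Raised when a gene name cannot be resolved against the vocabulary."""


def normalize_gene(name: str) -> str:
    """Resolve ``name`` to a canonical symbol, raising :class:`UnknownGeneError`."""
    key = _squash(name)
    try:
        return _alias_map()[key]
    except KeyError:
        raise UnknownGeneError(name) from None


def try_normalize_gene(name: str) -> str | None:
    """Like :func:`normalize_gene` but returns None on failure."""
    return _alias_map().get(_squash(name))
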