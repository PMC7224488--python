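"""mitoarch: comparative mitogenome architecture and composition toolkit."""

from importlib import resources

from .genome_io import AnnotatedGenome, GeneFeature, read_gene_table

__version__ = "0.1.0"

__all__ = [
    "AnnotatedGenome",
    "GeneFeature",
    "read_gene_table",
    "load_reference_genome",
]


def load_reference_genome(genome_id: str = "DH") -> AnnotatedGenome:
    """Load a bundled published gene-organization table (features only).

    Currently ships ``DH``, the Dendrolimus houi mitogenome annotation
    (15,373 bp, 37 genes + control region) with the published per-junction
    interval/overlap values carried as ``printed_gap``.
    """
    path = resources.files("mitoarch") / "data" / "dendrolimus_houi_table.tsv"
    with resources.as_file(path) as p:
        genomes = {g.genome_id: g for g in read_gene_table(p)}
    try:
        return genomes[genome_id]
    except KeyError:
        raise KeyError(
            f"no bundled genome {genome_id!r}; available: {sorted(genomes)}"
        ) from None
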