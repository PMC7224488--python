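# mitoarch

Comparative analysis toolkit for insect mitochondrial genomes: base
composition and strand skews, codon usage and RSCU under the invertebrate
mitochondrial code, gene-junction (overlap/spacer) accounting, gene-order
comparison, control-region motif scanning, and a lightweight
distance/neighbor-joining phylogeny layer — plus a seeded synthetic
mitogenome generator so every stage is testable offline.

## Modules

| module | what it does |
|---|---|
| `mitoarch.genome_io` | gene tables (TSV), FASTA, GenBank, JSON genome dumps; 1-based inclusive coordinates, J/N strand convention, controlled gene vocabulary with an editable alias table |
| `mitoarch.composition_stats` | base counts, A+T / G+C content, AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), codon-position composition |
| `mitoarch.codon_analysis` | strand-aware CDS extraction, start/stop codon tables with incomplete-stop (T / TA) detection, codon usage, amino-acid frequencies, RSCU |
| `mitoarch.genome_architecture` | per-junction gap/overlap records and summaries, printed-vs-computed cross-validation, duplicate-aware gene-order comparison, control-region motif / poly-T / tandem-repeat scan |
| `mitoarch.phylo_lite` | PCG supermatrix concatenation (PHYLIP/NEXUS), K2P distances, neighbor joining, Robinson–Foulds comparison |
| `mitoarch.synthetic_mitogenome` | seeded 37-gene mitogenome generator with planted junction plans, start/stop codons and control-region motifs (truth metadata included); sequence evolution along a tree (K2P or AT-biased equal-rate model) |

A published 15,373-bp reference annotation ships as package data and is
available via `mitoarch.load_reference_genome("DH")`.

## CLI

```sh
# dump the bundled reference annotation, then analyze it
mitoarch reference --genome-id DH --out dh.json
mitoarch architecture dh.json --out junctions.tsv --summary summary.json --cross-validate
mitoarch composition dh.json

# simulate a genome and push it through the full pipeline
mitoarch simulate --seed 42 --out-fasta g.fa --out-table g.tsv --out-json g.json --truth truth.json
mitoarch codons g.json --out usage.tsv --rscu rscu.tsv --startstop startstop.tsv
mitoarch cr-scan g.json --motif ATAGA --min-polyt 10
mitoarch order-compare dh.json g.json

# distance phylogeny from per-gene alignments
mitoarch simulate-tree --newick '((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);' \
    --length 500 --seed 3 --out genes/ND2.fa
mitoarch phylo --genes genes/ --out nj.nwk --matrix supermatrix.phy
mitoarch treecmp nj.nwk truth.nwk
```

`mitoarch ingest` converts GenBank flat files or FASTA + gene-table input
into the JSON genome documents the other commands consume.

## Conventions

- Coordinates are 1-based, fully inclusive; junction gap =
  `next.start − prev.end − 1` (negative = overlap, 0 = abutting).
- Strands are `J` (majority, +/F) and `N` (minority, −/R).
- Genetic code: NCBI translation table 5 (AGA/AGG = Ser, AUA = Met,
  UGA = Trp; stops TAA/TAG). RSCU uses full synonymous families
  (Leu 6, Ser 8) with Leu1/Leu2/Ser1/Ser2 labels retained for reporting.
- Junction summaries are linear from the first feature; the circular
  wrap-around junction is reported separately.
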