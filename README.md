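# mirseed

Annotation of genetic variants against miRNA gene architecture, seed-switch
detection, genomic-feature overlap, and inbred-strain association scans.

## The problem

miRNAs repress their targets mainly through the **seed region** —
nucleotides 2–7 (6mer) or 2–8 (7mer) from the 5′ end of the mature miRNA.
A polymorphism inside a seed can therefore rewire an entire target
repertoire, and in the extreme case convert one miRNA's seed into the seed
of a *different* annotated miRNA (a **seed switch**: the classic example
is a mature-position-5 G>A in miR-96 whose mutant seed perfectly matches
miR-514). `mirseed` is a local, file-based toolkit for researchers who
want to screen variant sets against miRNA annotation:

- classify each variant by region — `seed`, `mature_nonseed`, `precursor`,
  or `outside` — with full plus/minus-strand coordinate handling between
  the genome, hairpin, and mature frames;
- type single-nucleotide substitutions as transitions (purine↔purine,
  pyrimidine↔pyrimidine) or transversions (purine↔pyrimidine);
- merge genomically adjacent SNVs within one hairpin into
  double-nucleotide polymorphisms (DNPs) and longer MNP runs;
- detect seed switches by exact 6mer/7mer seed-string matching against an
  index of all annotated seeds;
- intersect polymorphic miRNA genes with QTL, fragile sites, and host
  genes (sense/antisense orientation; exonic/intronic/exon-and-intron
  context against the merged exon union);
- scan phenotype panels from inbred strains with the nested fixed-effects
  linear model

  *y<sub>ijkl</sub>* = *μ* + *G<sub>i</sub>* + *L<sub>j(i)</sub>* +
  *S<sub>k</sub>* + *e<sub>ijkl</sub>*

  (genotype, strain nested within genotype, sex, residual), reporting the
  genotype effect as the coding-invariant difference of least-squares
  means with a two-sided p-value per trait.

Inputs are standard formats: miRBase-style GFF3 (hairpins with nested
matures), hairpin FASTA (DNA or RNA alphabet), VCF 4.x, BED3/4, gene/exon
GFF3, and a delimited phenotype table. A fixture generator
(`mirseed.simulate`) emits complete synthetic datasets with
machine-readable ground truth, so every stage is testable without any
database download.

## Worked example

The packaged canonical fixture reproduces the miR-96 → miR-514 seed-switch
relationship (published mature sequences, synthetic hairpin context for
the acceptor):

```sh
python - <<'EOF'
from mirseed.simulate import mir96_like_fixture
mir96_like_fixture("example")
EOF
mirseed annotate --gff example/mir96_like.gff3 --fasta example/mir96_like.fa \
    --vcf example/mir96_like.vcf -o catalog.tsv
mirseed seed-switch --gff example/mir96_like.gff3 --fasta example/mir96_like.fa \
    --vcf example/mir96_like.vcf -o switches.tsv
```

`catalog.tsv` contains one row: the variant at chr7:129414597 (C>T on the
plus strand) maps to mature position 5 of the minus-strand miR-96-like
mature, inside both seed definitions, with transcript-oriented alleles
G>A — a transition:

```
chrom  start      variant_id        vclass  mature       region  mature_position  substitution  ref_rna  alt_rna
chr7   129414597  var_mir96_plus13  snv     miR-96-like  seed    5                transition    G        A
```

`switches.tsv` shows that the mutant seed equals the miR-514-like seed for
both seed definitions:

```
variant_id        source_mature  k  wildtype_seed  mutant_seed  matched_mirnas
var_mir96_plus13  miR-96-like    6  UUGGCA         UUGACA       miR-514-like
var_mir96_plus13  miR-96-like    7  UUGGCAC        UUGACAC      miR-514-like
```

The other subcommands follow the same pattern: `mirseed overlap`,
`mirseed host-context`, `mirseed assoc`, and `mirseed simulate` (see
`mirseed --help`). Everything is also available as library functions
(`mirseed.annotate`, `mirseed.find_seed_switches`, `mirseed.scan_traits`,
…).

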