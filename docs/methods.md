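# Methods

## Coordinate model

All internal coordinates are 1-based inclusive, the native convention of
GFF3 and VCF; BED's 0-based half-open intervals are converted once at the
I/O boundary (`start+1`, `end`) and converted back on write, a bijection
verified by property test. Hairpin sequences are stored in transcript
(5′→3′) orientation in the RNA alphabet, matching miRBase FASTA; genomic
strand enters only the coordinate arithmetic. For a mature spanning
genomic `[s, e]`, mature position of genomic position `g` is `g − s + 1`
on the plus strand and `e − g + 1` on the minus strand; the inverse map
is used to derive the genomic span of a seed. Variant alleles are stored
as given in the VCF (plus-strand DNA) for provenance and converted to
transcript-oriented RNA (`T→U`, reverse complement on minus-strand
hairpins) for every intra-miRNA comparison.

## Variant normalization and classes

VCF records are expanded to one variant per ALT allele. Shared leading and
trailing bases are trimmed; the VCF anchor base of an indel is stripped,
so a deletion's `ref` holds exactly the deleted bases and a pure insertion
has an empty `ref`. Classes are derived from allele lengths: `snv` (1:1),
`mnp` (equal length > 1), `insertion`, `deletion`. Structurally corrupt
VCF lines fail the parse (the underlying htslib parser is strict);
records with symbolic or non-ACGTN alleles are skipped and logged.

Region membership of a variant is decided by the set of *reference* bases
it affects: the substituted bases for SNV/MNP, the deleted span for
deletions, and the two flanking reference bases for insertions — so an
insertion strictly between two seed positions counts as seed. A variant
is `seed` for a given mature if any affected base maps to mature
positions 2–8; membership in positions 2–7 (6mer) and 2–8 (7mer) is
carried separately, since both seed definitions are in common use and the
choice matters exactly at position 8. Position 1 is never seed. A variant
inside two overlapping matures is reported once per mature (seed
membership is mature-specific); one inside the hairpin but no mature is
`precursor`. A REF allele that disagrees with the hairpin sequence flags
the annotation rather than aborting — public variant sets and miRNA
builds can disagree — and flagged records are excluded from seed-switch
screening.

Transition/transversion is classified on transcript-oriented alleles;
the class is complement-invariant (A↔G maps to U↔C), so strand handling
cannot change it (verified exhaustively).

## DNP merging

SNVs at genomically adjacent positions within one hairpin are grouped
into maximal runs: runs of length 2 are labeled `DNP`, longer runs
`MNP<len>`. Original per-SNV records are retained and one derived merged
record (concatenated alleles, lexicographically first ALT per position
when a position is multiallelic) is added per run. VCF records already
encoding a length-2 MNP get the `DNP` label directly, so both
representations — one MNP record or two adjacent SNV records — produce
the same labels. The operation is idempotent and order-invariant.

## Seed-switch detection

All mature seeds of length k ∈ {6, 7} are indexed by exact string; seed
families (matures sharing a seed) share a key and every member is
reported on a hit. For each seed substitution (SNV or MNP; indels change
seed length and are out of scope) the mutant mature sequence is computed
and its k-mer seed looked up. A hit requires that the variant actually
changes that k-mer — a variant at mature position 8 can only produce a
7mer switch — and that the mutant seed belongs to at least one *other*
mature; self-matches are suppressed. Matching is exact, so recall and
precision against planted truth involve no tolerance. Because the 6mer is
a prefix of the 7mer, every 7mer match implies the corresponding 6mer
match; both are reported separately rather than guessing a single
definition.

## Feature overlap and host-gene context

Overlap is computed at the hairpin level — one shared base between the
pre-miRNA span and the feature suffices — since QTL and fragile sites are
orders of magnitude larger than a seed; full containment is available as
a flag. QTL and fragile sites are treated as unstranded. Host-gene
orientation is `sense` when strands agree; context is classified against
the merged exon union of the gene (avoiding transcript-isoform double
counting): `exonic` when the hairpin lies fully inside the union,
`intronic` when it shares no base with it, `exon_and_intron` otherwise —
a partition verified against a per-base membership oracle.

## Association model

For one trait measured on an inbred-strain panel,

y_ijkl = μ + G_i + L_j(i) + S_k + e_ijkl,

with genotype G (two levels), strain L nested within genotype (inbred
strains carry a single genotype, so strain determines genotype), sex S,
and i.i.d. residual error. The fit is ordinary least squares on the
full-rank strain + sex design; the genotype effect is reported as the
difference of genotype least-squares means (the unweighted average of
strain means within each genotype, second sorted genotype level minus the
first), which is invariant to the coding and reduces to the raw
difference of genotype means under a balanced design. The default test
divides by the residual mean square (the default of the major commercial
GLM implementations); `strain_error=True` uses the strain-within-genotype
mean square with `n_strains − 2` degrees of freedom, the classical choice
when strains rather than individual animals are the experimental units —
strictly more conservative whenever real strain heterogeneity exists.
Traits observed in one sex drop the sex term with a note; traits with a
single genotype level or a single strain return a "not estimable" result
rather than raising; zero-variance traits return effect 0 and p = 1 by
convention (avoiding 0/0 F statistics). The multi-trait scan reports raw
two-sided p-values and flags p < α (default α = 0.01) without
multiple-testing correction — the scan is a prioritization screen, not a
causal claim — with optional Benjamini–Hochberg adjustment. Input may be
individual measurements or strain means; the denominator choice is
surfaced for exactly that reason.

## Synthetic fixtures

The generator emits a complete dataset (genome and hairpin FASTA, miRNA
GFF3, VCF, QTL/fragile-site BED, gene GFF3, phenotype TSV) plus a
ground-truth JSON. Defaults: 2 chromosomes of 50 kb with i.i.d. uniform
bases, 30 hairpins of 70–100 nt (half on the minus strand) each with a 5p
and a 3p mature of 20–23 nt; planted SNVs per region class, anchored
deletions and insertions inside matures, adjacent-SNV runs of length 2
and 3 in precursor regions, and seed-switch pairs constructed by copying
a donor 7mer seed into an acceptor mature except at one position, then
emitting the single substitution that completes the copy. Ground truth is
recorded by construction and by generator-internal enumeration (plain
double loops over its own sequences), never by calling the code under
test. Random seeds collide (4⁶ = 4096 6mer keys), so accidental seed
sharing and accidental switch hits are enumerated post hoc and recorded
— the truth file stays truthful, and detection is scored against the full
expectation set.

The phenotype block emulates a 14-strain panel split 7/7 between two
genotypes, both sexes, 10 observations per cell, an additive genotype
effect of 2.0 trait units on effect traits against unit residual noise,
and a small sex effect. A strain-variance knob exists but defaults to 0:
with real strain heterogeneity the residual-denominator test is
deliberately anticonservative (that is the point of the `strain_error`
option), so the default conditions keep the null calibration meaningful.
What these fixtures do *not* emulate: hairpin thermodynamics, realistic
chromosome lengths or base composition, linkage between variants, and
measurement structure of real phenotype resources (unbalanced cells,
correlated traits). Passing tests therefore demonstrate correctness of
the coordinate arithmetic, classification logic, and model algebra — not
robustness to the messiness of real annotation releases.

The canonical worked example packages the published miR-96 and miR-514
mature sequences (the acceptor hairpin context is synthetic, and names
carry a `-like` suffix to say so), places the miR-96-like gene on the
minus strand at its published span, and plants the mature-position-5 G>A
substitution (precursor position +13, C>T on the plus strand).

## Numerical and scale choices

Exact string and integer comparisons are used throughout the annotation
path; the only tolerances are in the association tests (1e-8 for the
balanced-design identity, two empirical SDs for 200-simulation effect
recovery, the exact binomial 95% interval for the 5000-trait null
calibration at α = 0.01). Test problem sizes — 200 miRNAs × 2000 variants
for the annotation oracle, 500 miRNAs × 50 planted switches × 200
features for detection and overlap, 5000 null traits with 4 observations
per cell, 20 end-to-end fixture seeds — were chosen to exercise every
code path at desk scale; the acceptance script uses a 2000-trait null
scan and 5 end-to-end seeds, which it completes in well under a minute.
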