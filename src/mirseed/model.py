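"""Domain model: genomic intervals, miRNA hairpins/matures, and seed-region
coordinate arithmetic.

Coordinate conventions
----------------------
All internal coordinates are 1-based inclusive (GFF3/VCF native).  BED input
is converted at the I/O boundary.  Hairpin sequences are stored in transcript
(5'->3') orientation in the RNA alphabet ``{A, C, G, U}``, matching the
miRBase FASTA convention; genomic strand inversion happens only in
coordinate math, never in sequence storage.

The seed region of a mature miRNA is nucleotides 2-7 (6mer) or 2-8 (7mer)
counted from its 5' end; position 1 is never part of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import complement_rna, reverse_complement_rna

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")
RNA_BASES = frozenset("ACGU")

SEED_KS = (6, 7)

#: Region classes a variant can fall into, from most to least specific.
REGION_SEED = "seed"
REGION_MATURE = "mature_nonseed"
REGION_PRECURSOR = "precursor"
REGION_OUTSIDE = "outside"


class ModelError(ValueError):
    """Raised when a domain invariant is violated."""


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelError("chromosome name must be nonempty")
        if self.start > self.end:
            raise ModelError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ModelError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class GenomicFeature:
    """A QTL, fragile site, gene, or exon used in overlap analyses.

    Exons must carry a ``parent`` gene identifier; other kinds must not.
    """

    interval: GenomicInterval
    kind: str  # qtl | fragile_site | gene | exon
    name: str
    parent: Optional[str] = None

    KINDS = ("qtl", "fragile_site", "gene", "exon")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ModelError(f"unknown feature kind {self.kind!r}")
        if self.kind == "exon" and self.parent is None:
            raise ModelError(f"exon {self.name!r} lacks a parent gene")
        if self.kind != "exon" and self.parent is not None:
            raise ModelError(f"{self.kind} {self.name!r} must not carry a parent")


@dataclass(frozen=True)
class Variant:
    """A genomic variant with alleles given on the + strand.

    One object per ALT allele; multiallelic VCF records are expanded at
    parse time.  Indels are normalized: the shared VCF anchor base is
    stripped, so a pure insertion has an empty ``ref`` and its interval
    spans the two flanking reference bases, and a pure deletion's ``ref``
    holds exactly the deleted bases.
    """

    id: str
    interval: GenomicInterval
    ref: str
    alt: str

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.ref) == len(self.alt) and len(self.ref) > 1:
            return "mnp"
        if len(self.ref) < len(self.alt):
            return "insertion"
        return "deletion"

    def affected_positions(self) -> range:
        """Reference positions whose identity decides region membership.

        Substitutions affect the substituted bases; deletions the deleted
        span; insertions the two flanking reference bases (an insertion
        strictly between two seed positions counts as seed).
        """
        return range(self.interval.start, self.interval.end + 1)


@dataclass
class MatureMir:
    """A mature miRNA ("miR" naming convention) nested in its hairpin."""

    name: str
    interval: GenomicInterval
    hairpin_offset: int  # 1-based start within the hairpin sequence
    length: int

    def __post_init__(self) -> None:
        if self.hairpin_offset < 1:
            raise ModelError(f"mature {self.name}: hairpin_offset must be >= 1")
        if len(self.interval) != self.length:
            raise ModelError(
                f"mature {self.name}: genomic span {len(self.interval)} != "
                f"length {self.length}"
            )


@dataclass
class MirnaHairpin:
    """A pre-miRNA locus ("mir" naming convention) with nested matures.

    ``sequence`` may be attached later (after FASTA pairing); when present
    its length must equal the genomic span.
    """

    name: str
    interval: GenomicInterval
    sequence: Optional[str] = None
    matures: list[MatureMir] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ModelError(f"hairpin {self.name}: strand must be + or -")
        self.validate()

    def validate(self) -> None:
        if self.sequence is not None and len(self.sequence) != len(self.interval):
            raise ModelError(
                f"hairpin {self.name}: sequence length {len(self.sequence)} != "
                f"genomic span {len(self.interval)}"
            )
        for m in self.matures:
            if (
                m.interval.chrom != self.interval.chrom
                or m.interval.start < self.interval.start
                or m.interval.end > self.interval.end
            ):
                raise ModelError(
                    f"mature {m.name} span {m.interval.start}-{m.interval.end} "
                    f"exceeds hairpin {self.name} span "
                    f"{self.interval.start}-{self.interval.end}"
                )
            if m.interval.strand != self.interval.strand:
                raise ModelError(
                    f"mature {m.name} strand differs from hairpin {self.name}"
                )
            if m.hairpin_offset + m.length - 1 > len(self.interval):
                raise ModelError(
                    f"mature {m.name} extends past hairpin {self.name} sequence"
                )


@dataclass(frozen=True)
class SeedRegion:
    """The seed of a mature miRNA: positions 2..k+1 from the 5' end."""

    mature: MatureMir
    k: int
    genomic_interval: GenomicInterval
    seed_sequence: str

    @property
    def mature_positions(self) -> range:
        return range(2, self.k + 2)


# ---------------------------------------------------------------------------
# Coordinate arithmetic between genome, hairpin, and mature frames
# ---------------------------------------------------------------------------


def hairpin_offset_from_genome(hairpin: MirnaHairpin, gpos: int) -> Optional[int]:
    """1-based position within the hairpin sequence, or None if outside."""
    if not hairpin.interval.contains(gpos):
        return None
    if hairpin.interval.strand == "+":
        return gpos - hairpin.interval.start + 1
    return hairpin.interval.end - gpos + 1


def mature_sequence(hairpin: MirnaHairpin, mature: MatureMir) -> str:
    """The mature sequence, 5'->3', sliced from the stored hairpin sequence.

    The hairpin sequence is stored in transcript orientation, so no strand
    handling is needed here.
    """
    if hairpin.sequence is None:
        raise ModelError(f"hairpin {hairpin.name} has no sequence attached")
    lo = mature.hairpin_offset - 1
    return hairpin.sequence[lo : lo + mature.length]


def genome_to_mature_position(
    mature: MatureMir, hairpin: MirnaHairpin, gpos: int
) -> Optional[int]:
    """Map a genomic position to a 1-based position within the mature.

    Returns None when ``gpos`` falls outside the mature span.  On the minus
    strand the mature's 5' end is its highest genomic coordinate.
    """
    if not mature.interval.contains(gpos):
        return None
    if hairpin.interval.strand == "+":
        return gpos - mature.interval.start + 1
    return mature.interval.end - gpos + 1


def mature_to_genome_position(
    mature: MatureMir, hairpin: MirnaHairpin, mpos: int
) -> int:
    """Inverse of :func:`genome_to_mature_position`."""
    if not 1 <= mpos <= mature.length:
        raise ModelError(
            f"mature position {mpos} outside 1..{mature.length} of {mature.name}"
        )
    if hairpin.interval.strand == "+":
        return mature.interval.start + mpos - 1
    return mature.interval.end - mpos + 1


def extract_seed(mature_seq: str, k: int = 7) -> str:
    """Seed of a mature sequence: positions 2..k+1 (k = 6 or 7)."""
    if k not in SEED_KS:
        raise ModelError(f"seed length k must be 6 or 7, got {k}")
    if len(mature_seq) < k + 1:
        raise ModelError(
            f"mature sequence of length {len(mature_seq)} too short for "
            f"{k}mer seed (needs >= {k + 1} nt)"
        )
    return mature_seq[1 : k + 1]


def seed_region(mature: MatureMir, hairpin: MirnaHairpin, k: int = 7) -> SeedRegion:
    """Seed region with both its mature-frame and genomic coordinates."""
    if mature.length < k + 1:
        raise ModelError(
            f"mature {mature.name} ({mature.length} nt) too short for "
            f"{k}mer seed"
        )
    seq = extract_seed(mature_sequence(hairpin, mature), k)
    g1 = mature_to_genome_position(mature, hairpin, 2)
    g2 = mature_to_genome_position(mature, hairpin, k + 1)
    gi = GenomicInterval(
        mature.interval.chrom, min(g1, g2), max(g1, g2), hairpin.interval.strand
    )
    return SeedRegion(mature=mature, k=k, genomic_interval=gi, seed_sequence=seq)


def transcript_allele(allele_dna: str, strand: str) -> str:
    """Convert a + strand DNA allele to transcript-oriented RNA.

    Minus-strand transcripts see the reverse complement of the + strand
    allele string.
    """
    rna = dna_to_rna(allele_dna)
    if strand == "-":
        rna = reverse_complement_rna(rna)
    return rna


__all__ = [
    "GenomicInterval",
    "GenomicFeature",
    "Variant",
    "MatureMir",
    "MirnaHairpin",
    "SeedRegion",
    "ModelError",
    "PURINES",
    "PYRIMIDINES",
    "RNA_BASES",
    "SEED_KS",
    "REGION_SEED",
    "REGION_MATURE",
    "REGION_PRECURSOR",
    "REGION_OUTSIDE",
    "dna_to_rna",
    "rna_to_dna",
    "hairpin_offset_from_genome",
    "mature_sequence",
    "genome_to_mature_position",
    "mature_to_genome_position",
    "extract_seed",
    "seed_region",
    "transcript_allele",
    "complement_rna",
    "reverse_complement_rna",
]
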