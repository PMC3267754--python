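"""Variant annotation against miRNA gene architecture.

Each variant is classified by the region of the miRNA gene it hits —
seed (mature positions 2-8), mature outside the seed, precursor hairpin,
or outside any hairpin — and, for single-nucleotide substitutions, as a
transition or transversion.  Adjacent SNVs within one hairpin are merged
into double-nucleotide polymorphism (DNP) runs.

Region membership of an indel is decided by the set of reference bases it
affects: the deleted span for deletions, the two flanking bases for
insertions (so an insertion strictly between two seed positions counts as
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .model import (
    GenomicInterval,
    MirnaHairpin,
    ModelError,
    PURINES,
    PYRIMIDINES,
    REGION_MATURE,
    REGION_OUTSIDE,
    REGION_PRECURSOR,
    REGION_SEED,
    RNA_BASES,
    Variant,
    genome_to_mature_position,
    hairpin_offset_from_genome,
    transcript_allele,
)

#: mature positions forming the 6mer and 7mer seeds
SEED6_POSITIONS = range(2, 8)   # 2..7
SEED7_POSITIONS = range(2, 9)   # 2..8


@dataclass
class AnnotatedVariant:
    """A variant decorated with its miRNA-architecture context.

    One record per (variant, mature) pair; a variant inside a hairpin but
    outside every mature gets a single record with ``mature=None``.
    """

    variant: Variant
    hairpin: Optional[str]
    mature: Optional[str]
    region: str
    strand: str = "."
    mature_position: Optional[int] = None
    seed6_member: bool = False
    seed7_member: bool = False
    substitution: Optional[str] = None  # transition | transversion (SNVs only)
    ref_rna: Optional[str] = None
    alt_rna: Optional[str] = None
    dnp_group: Optional[str] = None
    ref_mismatch: bool = False
    validation_status: Optional[str] = None


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) vs transversion
    (purine<->pyrimidine), on RNA bases."""
    if ref_base not in RNA_BASES or alt_base not in RNA_BASES:
        raise ModelError(f"non-RNA base in substitution {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ModelError(f"identical alleles {ref_base!r}")
    same_class = (ref_base in PURINES) == (alt_base in PURINES)
    return "transition" if same_class else "transversion"


def classify_region(
    variant: Variant, hairpin: MirnaHairpin
) -> list[AnnotatedVariant]:
    """Classify one variant against one hairpin.

    Returns one annotation per mature the variant touches (a variant inside
    two overlapping matures is reported once per mature), or a single
    precursor/outside annotation.
    """
    strand = hairpin.interval.strand
    affected = [
        p for p in variant.affected_positions() if hairpin.interval.contains(p)
    ]
    ref_rna = transcript_allele(variant.ref, strand) if variant.ref else ""
    alt_rna = transcript_allele(variant.alt, strand) if variant.alt else ""
    substitution = None
    if variant.vclass == "snv":
        substitution = classify_substitution(ref_rna, alt_rna)

    if not affected:
        return [
            AnnotatedVariant(
                variant=variant,
                hairpin=None,
                mature=None,
                region=REGION_OUTSIDE,
                substitution=substitution,
            )
        ]

    ref_mismatch = _check_ref(variant, hairpin)

    annotations: list[AnnotatedVariant] = []
    for mature in hairpin.matures:
        mpos = [
            mp
            for p in affected
            if (mp := genome_to_mature_position(mature, hairpin, p)) is not None
        ]
        if not mpos:
            continue
        seed6 = any(mp in SEED6_POSITIONS for mp in mpos)
        seed7 = any(mp in SEED7_POSITIONS for mp in mpos)
        region = REGION_SEED if seed7 else REGION_MATURE
        annotations.append(
            AnnotatedVariant(
                variant=variant,
                hairpin=hairpin.name,
                mature=mature.name,
                region=region,
                strand=strand,
                mature_position=min(mpos),
                seed6_member=seed6,
                seed7_member=seed7,
                substitution=substitution,
                ref_rna=ref_rna,
                alt_rna=alt_rna,
                ref_mismatch=ref_mismatch,
            )
        )
    if not annotations:
        annotations.append(
            AnnotatedVariant(
                variant=variant,
                hairpin=hairpin.name,
                mature=None,
                region=REGION_PRECURSOR,
                strand=strand,
                substitution=substitution,
                ref_rna=ref_rna,
                alt_rna=alt_rna,
                ref_mismatch=ref_mismatch,
            )
        )
    return annotations


def _check_ref(variant: Variant, hairpin: MirnaHairpin) -> bool:
    """True when the variant's REF disagrees with the hairpin sequence.

    Checked only when the sequence is attached, the variant carries
    reference bases, and its footprint lies fully inside the hairpin.
    Mismatches flag the annotation (public variant sets and miRNA builds
    can disagree); they never abort.
    """
    if hairpin.sequence is None or not variant.ref:
        return False
    span = variant.interval
    if not (hairpin.interval.contains(span.start) and hairpin.interval.contains(span.end)):
        return False
    offsets = sorted(
        hairpin_offset_from_genome(hairpin, p)
        for p in range(span.start, span.end + 1)
    )
    observed = hairpin.sequence[offsets[0] - 1 : offsets[-1]]
    expected = transcript_allele(variant.ref, hairpin.interval.strand)
    return observed != expected


def annotate(
    variants: Sequence[Variant],
    mirnas: Sequence[MirnaHairpin],
    include_outside: bool = False,
) -> list[AnnotatedVariant]:
    """Annotate every variant against every hairpin it overlaps.

    Hairpins are indexed by interval tree per chromosome; a variant
    overlapping no hairpin yields an ``outside`` record only when
    ``include_outside`` is set.  Output order is deterministic.
    """
    trees: dict[str, IntervalTree] = {}
    for hp in mirnas:
        trees.setdefault(hp.interval.chrom, IntervalTree()).addi(
            hp.interval.start, hp.interval.end + 1, hp
        )
    out: list[AnnotatedVariant] = []
    for v in variants:
        tree = trees.get(v.interval.chrom)
        hits = (
            sorted(
                (iv.data for iv in tree.overlap(v.interval.start, v.interval.end + 1)),
                key=lambda h: (h.interval.start, h.name),
            )
            if tree
            else []
        )
        if not hits:
            if include_outside:
                substitution = None
                if v.vclass == "snv":
                    substitution = classify_substitution(
                        transcript_allele(v.ref, "+"), transcript_allele(v.alt, "+")
                    )
                out.append(
                    AnnotatedVariant(
                        variant=v,
                        hairpin=None,
                        mature=None,
                        region=REGION_OUTSIDE,
                        substitution=substitution,
                    )
                )
            continue
        for hp in hits:
            out.extend(classify_region(v, hp))
    out.sort(key=_annotation_key)
    return out


def _annotation_key(a: AnnotatedVariant):
    v = a.variant
    return (
        v.interval.chrom,
        v.interval.start,
        a.hairpin or "",
        a.mature or "",
        v.id,
        v.alt,
    )


# ---------------------------------------------------------------------------
# DNP / MNP-run merging
# ---------------------------------------------------------------------------


def merge_dnps(annotated: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Group genomically adjacent SNVs within one hairpin into maximal runs.

    Runs of length 2 are labeled ``DNP``, longer runs ``MNP<len>``; the
    original per-SNV records are retained and one derived merged record is
    added per run.  VCF MNP records of length 2 are labeled ``DNP`` directly.
    The operation is idempotent and independent of input order.
    """
    out = [replace(a) for a in annotated]

    # direct path: length-2 MNP records are DNPs by definition
    for a in out:
        if a.variant.vclass == "mnp" and len(a.variant.ref) == 2 and a.dnp_group is None:
            a.dnp_group = f"DNP:{a.variant.interval.chrom}:{a.variant.interval.start}"

    # adjacency path: group SNV records per hairpin
    by_hairpin: dict[str, list[AnnotatedVariant]] = {}
    for a in out:
        if a.hairpin is not None and a.variant.vclass == "snv" and not _is_derived(a):
            by_hairpin.setdefault(a.hairpin, []).append(a)

    derived: list[AnnotatedVariant] = []
    existing = {_identity(a) for a in out}
    for hairpin_name, anns in sorted(by_hairpin.items()):
        by_pos: dict[int, list[AnnotatedVariant]] = {}
        for a in anns:
            by_pos.setdefault(a.variant.interval.start, []).append(a)
        positions = sorted(by_pos)
        run: list[int] = []
        for pos in positions + [None]:  # sentinel flushes the last run
            if run and (pos is None or pos != run[-1] + 1):
                if len(run) >= 2:
                    label = (
                        f"DNP:{anns[0].variant.interval.chrom}:{run[0]}"
                        if len(run) == 2
                        else f"MNP{len(run)}:{anns[0].variant.interval.chrom}:{run[0]}"
                    )
                    for p in run:
                        for a in by_pos[p]:
                            a.dnp_group = label
                    derived.extend(
                        _merged_records(hairpin_name, run, by_pos, label, existing)
                    )
                run = []
            if pos is not None:
                run.append(pos)
    out.extend(derived)
    out.sort(key=_annotation_key)
    return out


def _is_derived(a: AnnotatedVariant) -> bool:
    return a.variant.id.startswith("merged:")


def _identity(a: AnnotatedVariant):
    v = a.variant
    return (v.id, v.interval.chrom, v.interval.start, v.ref, v.alt, a.mature)


def _merged_records(
    hairpin_name: str,
    run: list[int],
    by_pos: dict[int, list[AnnotatedVariant]],
    label: str,
    existing: set,
) -> list[AnnotatedVariant]:
    """One derived multi-base substitution record per run, built from the
    lexicographically first alternate allele at each position."""
    chosen = [
        min(by_pos[p], key=lambda a: a.variant.alt) for p in run
    ]
    chrom = chosen[0].variant.interval.chrom
    merged = Variant(
        id="merged:" + "+".join(
            dict.fromkeys(a.variant.id for a in chosen)
        ),
        interval=GenomicInterval(chrom, run[0], run[-1], "."),
        ref="".join(a.variant.ref for a in chosen),
        alt="".join(a.variant.alt for a in chosen),
    )
    records = []
    template = chosen[0]
    ann = AnnotatedVariant(
        variant=merged,
        hairpin=hairpin_name,
        mature=None,
        region=REGION_PRECURSOR,
        strand=template.strand,
        dnp_group=label,
    )
    key = _identity(ann)
    if key not in existing:
        existing.add(key)
        records.append(ann)
    return records


def titv_counts(annotated: Sequence[AnnotatedVariant]) -> tuple[int, int]:
    """(transitions, transversions) over the annotated SNVs; their sum
    equals the number of annotated SNV records."""
    ti = sum(1 for a in annotated if a.substitution == "transition")
    tv = sum(1 for a in annotated if a.substitution == "transversion")
    return ti, tv
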