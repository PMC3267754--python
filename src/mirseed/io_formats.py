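"""Readers and writers for the external formats the toolkit touches.

All parsing goes through established format libraries (gffutils for GFF3,
Biopython for FASTA, pysam for VCF, pandas for tabular files); this module
only normalizes their output into the internal model:

* coordinates: internal model is 1-based inclusive; BED (0-based half-open)
  is converted here and nowhere else;
* alphabets: hairpin sequences are normalized to RNA (T->U, uppercase);
  VCF alleles stay as given (+ strand DNA) for provenance.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    GenomicFeature,
    GenomicInterval,
    MatureMir,
    MirnaHairpin,
    ModelError,
    Variant,
    dna_to_rna,
)

logger = logging.getLogger("mirseed")

#: GFF3 feature types of the miRBase dialect.
HAIRPIN_TYPE = "miRNA_primary_transcript"
MATURE_TYPE = "miRNA"

#: Columns of the output catalog, in order.
CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "variant_id",
    "ref",
    "alt",
    "vclass",
    "hairpin",
    "mature",
    "region",
    "mature_position",
    "seed6_member",
    "seed7_member",
    "substitution",
    "ref_rna",
    "alt_rna",
    "dnp_group",
    "ref_mismatch",
    "validation_status",
]


# ---------------------------------------------------------------------------
# miRNA GFF3
# ---------------------------------------------------------------------------


def read_mirna_gff(path: str | Path) -> list[MirnaHairpin]:
    """Parse a miRBase-style GFF3 into hairpins with nested matures.

    Hairpins are ``miRNA_primary_transcript`` records; matures are ``miRNA``
    records pointing at their hairpin via ``Derives_from`` (or ``Parent``).
    A mature with no resolvable hairpin, or one whose span exceeds its
    hairpin, is rejected with an error naming the record.  Unknown GFF3
    attributes are preserved as opaque metadata on the hairpin.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    hairpins: dict[str, MirnaHairpin] = {}
    by_name: dict[str, str] = {}
    for feat in db.features_of_type(HAIRPIN_TYPE, order_by=("seqid", "start")):
        name = feat.attributes.get("Name", [feat.id])[0]
        meta = {
            k: ",".join(v)
            for k, v in feat.attributes.items()
            if k not in ("ID", "Name")
        }
        hp = MirnaHairpin(
            name=name,
            interval=GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand),
            metadata=meta,
        )
        hairpins[feat.id] = hp
        by_name[name] = feat.id
    for feat in db.features_of_type(MATURE_TYPE, order_by=("seqid", "start")):
        name = feat.attributes.get("Name", [feat.id])[0]
        parent_ids = feat.attributes.get("Derives_from") or feat.attributes.get(
            "Parent"
        )
        if not parent_ids:
            raise ModelError(f"mature record {name!r} has no parent hairpin")
        pid = parent_ids[0]
        hp = hairpins.get(pid) or hairpins.get(by_name.get(pid, ""))
        if hp is None:
            raise ModelError(
                f"mature record {name!r} references unknown hairpin {pid!r}"
            )
        if feat.start < hp.interval.start or feat.end > hp.interval.end:
            raise ModelError(
                f"mature {name!r} span {feat.start}-{feat.end} exceeds hairpin "
                f"{hp.name!r} span {hp.interval.start}-{hp.interval.end}"
            )
        if hp.interval.strand == "+":
            offset = feat.start - hp.interval.start + 1
        else:
            offset = hp.interval.end - feat.end + 1
        hp.matures.append(
            MatureMir(
                name=name,
                interval=GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand),
                hairpin_offset=offset,
                length=feat.end - feat.start + 1,
            )
        )
    out = list(hairpins.values())
    for hp in out:
        hp.matures.sort(key=lambda m: m.hairpin_offset)
        hp.validate()
    return out


def write_mirna_gff(hairpins: Sequence[MirnaHairpin], path: str | Path) -> None:
    """Write hairpins and their matures back out as miRBase-style GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, hp in enumerate(
            sorted(hairpins, key=lambda h: (h.interval.chrom, h.interval.start))
        ):
            hid = f"MI{i:07d}"
            attrs = [f"ID={hid}", f"Name={hp.name}"]
            attrs += [f"{k}={v}" for k, v in sorted(hp.metadata.items())]
            fh.write(
                "\t".join(
                    [
                        hp.interval.chrom,
                        "mirseed",
                        HAIRPIN_TYPE,
                        str(hp.interval.start),
                        str(hp.interval.end),
                        ".",
                        hp.interval.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for j, m in enumerate(hp.matures):
                mid = f"MIMAT{i:05d}_{j}"
                fh.write(
                    "\t".join(
                        [
                            m.interval.chrom,
                            "mirseed",
                            MATURE_TYPE,
                            str(m.interval.start),
                            str(m.interval.end),
                            ".",
                            m.interval.strand,
                            ".",
                            f"ID={mid};Name={m.name};Derives_from={hid}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# hairpin FASTA
# ---------------------------------------------------------------------------

_VALID_INPUT_BASES = frozenset("ACGUTN")


def read_hairpin_fasta(path: str | Path) -> dict[str, str]:
    """Read hairpin sequences, normalized to uppercase RNA.

    Accepts DNA or RNA alphabets (``T`` becomes ``U``); any character
    outside ``{A, C, G, U, T, N}`` (case-insensitive) is rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_INPUT_BASES
        if bad:
            raise ModelError(
                f"sequence {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        seqs[rec.id] = dna_to_rna(seq)
    return seqs


def write_hairpin_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(
    hairpins: Iterable[MirnaHairpin], seqs: dict[str, str]
) -> list[MirnaHairpin]:
    """Pair hairpins with their sequences, checking span/sequence length.

    A hairpin whose annotated span length disagrees with its sequence
    length is rejected at pairing time.
    """
    out = []
    for hp in hairpins:
        if hp.name not in seqs:
            raise ModelError(f"no sequence for hairpin {hp.name!r}")
        seq = seqs[hp.name]
        if len(seq) != len(hp.interval):
            raise ModelError(
                f"hairpin {hp.name!r}: sequence length {len(seq)} != annotated "
                f"span length {len(hp.interval)}"
            )
        hp.sequence = seq
        hp.validate()
        out.append(hp)
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_ALLELE_BASES = frozenset("ACGTN")


def _normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, int, str, str]:
    """Trim shared bases and resolve the VCF indel anchor.

    Returns ``(start, end, ref, alt)`` with 1-based inclusive coordinates.
    For pure insertions ``ref`` is empty and the interval spans the two
    flanking reference bases; for pure deletions ``alt`` is empty and the
    interval spans exactly the deleted bases.
    """
    # trim common suffix, then common prefix, keeping at least one base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt):
        return pos, pos + len(ref) - 1, ref, alt
    if ref and alt and ref[0] == alt[0]:
        if len(ref) < len(alt):  # insertion after the anchor base
            return pos, pos + 1, "", alt[1:]
        return pos + 1, pos + len(ref) - 1, ref[1:], ""  # deletion
    # complex allele without shared anchor: classify by reference footprint
    if not ref:
        return pos, pos + 1, "", alt
    return pos, pos + len(ref) - 1, ref, alt


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF 4.x into normalized variants, one per ALT allele.

    Multiallelic records are expanded.  Records with symbolic or otherwise
    unusable alleles are skipped and logged with their line position.
    """
    variants: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for lineno, rec in enumerate(vf, start=1):
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            ref = (rec.ref or "").upper()
            if not ref or set(ref) - _ALLELE_BASES:
                logger.warning("skipping record %d (%s): bad REF %r", lineno, vid, ref)
                continue
            for alt in rec.alts or ():
                alt = alt.upper()
                if not alt or set(alt) - _ALLELE_BASES:
                    logger.warning(
                        "skipping allele at record %d (%s): bad ALT %r",
                        lineno,
                        vid,
                        alt,
                    )
                    continue
                start, end, nref, nalt = _normalize_alleles(rec.pos, ref, alt)
                variants.append(
                    Variant(
                        id=vid,
                        interval=GenomicInterval(rec.chrom, start, end, "."),
                        ref=nref,
                        alt=nalt,
                    )
                )
    return variants


def write_vcf(
    records: Sequence[tuple[str, int, str, str, str]],
    contigs: dict[str, int],
    path: str | Path,
) -> None:
    """Write raw VCF records ``(chrom, pos, id, ref, alt_csv)`` with a
    minimal VCF 4.2 header carrying contig lengths."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, vid, ref, alt in sorted(records, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, kind: str = "qtl") -> list[GenomicFeature]:
    """Read BED3+ features, converting 0-based half-open to 1-based inclusive.

    Lines with ``start >= end`` are rejected (skipped and logged).
    """
    feats: list[GenomicFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, bstart, bend = fields[0], int(fields[1]), int(fields[2])
            if bstart >= bend:
                logger.warning(
                    "rejecting BED line %d: start %d >= end %d", lineno, bstart, bend
                )
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else (
                f"{kind}_{lineno}"
            )
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            feats.append(
                GenomicFeature(
                    interval=GenomicInterval(chrom, bstart + 1, bend, strand),
                    kind=kind,
                    name=name,
                )
            )
    return feats


def write_bed(features: Sequence[GenomicFeature], path: str | Path) -> None:
    """Write features as BED, converting back to 0-based half-open."""
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.interval.chrom, f.interval.start)):
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start - 1}\t{f.interval.end}"
                f"\t{f.name}\t0\t{f.interval.strand if f.interval.strand != '.' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def read_gene_gff(path: str | Path) -> list[GenomicFeature]:
    """Read gene/exon models from GFF3 into features; exons carry their
    parent gene's name."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    feats: list[GenomicFeature] = []
    id_to_name: dict[str, str] = {}
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        name = g.attributes.get("Name", [g.id])[0]
        id_to_name[g.id] = name
        feats.append(
            GenomicFeature(
                interval=GenomicInterval(g.seqid, g.start, g.end, g.strand),
                kind="gene",
                name=name,
            )
        )
    for e in db.features_of_type("exon", order_by=("seqid", "start")):
        parents = e.attributes.get("Parent")
        if not parents:
            raise ModelError(f"exon {e.id!r} has no Parent attribute")
        pname = id_to_name.get(parents[0], parents[0])
        feats.append(
            GenomicFeature(
                interval=GenomicInterval(e.seqid, e.start, e.end, e.strand),
                kind="exon",
                name=e.attributes.get("Name", [e.id])[0],
                parent=pname,
            )
        )
    return feats


def write_gene_gff(features: Sequence[GenomicFeature], path: str | Path) -> None:
    """Write gene/exon features as GFF3 (exons as children of genes)."""
    genes = [f for f in features if f.kind == "gene"]
    exons = [f for f in features if f.kind == "exon"]
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda f: (f.interval.chrom, f.interval.start)):
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "mirseed",
                        "gene",
                        str(g.interval.start),
                        str(g.interval.end),
                        ".",
                        g.interval.strand if g.interval.strand != "." else ".",
                        ".",
                        f"ID={g.name};Name={g.name}",
                    ]
                )
                + "\n"
            )
            for i, e in enumerate(
                sorted(
                    (e for e in exons if e.parent == g.name),
                    key=lambda f: f.interval.start,
                )
            ):
                fh.write(
                    "\t".join(
                        [
                            e.interval.chrom,
                            "mirseed",
                            "exon",
                            str(e.interval.start),
                            str(e.interval.end),
                            ".",
                            e.interval.strand if e.interval.strand != "." else ".",
                            ".",
                            f"ID={e.name};Name={e.name};Parent={g.name}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# annotation catalog (TSV)
# ---------------------------------------------------------------------------


def catalog_frame(annotated: Sequence) -> pd.DataFrame:
    """Annotated variants as a DataFrame with deterministic column order,
    sorted by chromosome, start, and miRNA name."""
    rows = []
    for a in annotated:
        v = a.variant
        rows.append(
            {
                "chrom": v.interval.chrom,
                "start": v.interval.start,
                "end": v.interval.end,
                "strand": a.strand,
                "variant_id": v.id,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "hairpin": a.hairpin or "",
                "mature": a.mature or "",
                "region": a.region,
                "mature_position": "" if a.mature_position is None else a.mature_position,
                "seed6_member": a.seed6_member,
                "seed7_member": a.seed7_member,
                "substitution": a.substitution or "",
                "ref_rna": a.ref_rna or "",
                "alt_rna": a.alt_rna or "",
                "dnp_group": a.dnp_group or "",
                "ref_mismatch": a.ref_mismatch,
                "validation_status": a.validation_status or "",
            }
        )
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["chrom", "start", "mature", "hairpin", "variant_id", "alt"]
        ).reset_index(drop=True)
    return df


def write_catalog(annotated: Sequence, path: str | Path) -> None:
    """Write the annotation catalog as TSV, one row per (variant, mature)."""
    catalog_frame(annotated).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    for col in ("seed6_member", "seed7_member", "ref_mismatch"):
        df[col] = df[col].map({"True": True, "False": False})
    return df


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["strain", "sex", "genotype", "trait", "group", "value"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a delimited phenotype table (strain, sex, genotype, trait,
    group, value)."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in PHENOTYPE_COLUMNS[:-1]})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ModelError(f"phenotype table missing columns {sorted(missing)}")
    df["value"] = df["value"].astype(float)
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)
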