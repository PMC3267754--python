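"""Overlap of polymorphic miRNA genes with genomic features.

Intersections are computed at the hairpin level (a shared base between the
pre-miRNA span and the feature counts), since QTL and fragile sites are
orders of magnitude larger than a 6-7 nt seed.  Host-gene context is
classified per gene: orientation (sense/antisense by strand agreement) and
exonic/intronic/exon_and_intron membership against the merged exon union
of the gene, so transcript isoforms are not double counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import GenomicFeature, GenomicInterval, MirnaHairpin, ModelError

logger = logging.getLogger("mirseed")


@dataclass(frozen=True)
class OverlapRecord:
    """One (miRNA, feature) pair sharing at least one base."""

    mirna: str
    feature: GenomicFeature
    orientation: str  # sense | antisense | unstranded
    context: Optional[str] = None  # exonic | intronic | exon_and_intron

    def __post_init__(self) -> None:
        if self.context is not None and self.feature.kind != "gene":
            raise ModelError("context applies to gene features only")


def _orientation(mirna_strand: str, feature_strand: str) -> str:
    if feature_strand == ".":
        return "unstranded"
    return "sense" if mirna_strand == feature_strand else "antisense"


def intersect(
    mirnas: Sequence[MirnaHairpin],
    features: Sequence[GenomicFeature],
    containment: bool = False,
) -> list[OverlapRecord]:
    """All (miRNA, feature) pairs with >= 1 shared base.

    With ``containment`` the miRNA hairpin must lie fully inside the
    feature.  Chromosomes present among the miRNAs but absent from the
    feature set are logged once.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.interval.chrom, IntervalTree()).addi(
            f.interval.start, f.interval.end + 1, f
        )
    missing_chroms: set[str] = set()
    records: list[OverlapRecord] = []
    for hp in mirnas:
        tree = trees.get(hp.interval.chrom)
        if tree is None:
            missing_chroms.add(hp.interval.chrom)
            continue
        for iv in tree.overlap(hp.interval.start, hp.interval.end + 1):
            f: GenomicFeature = iv.data
            if containment and not (
                f.interval.start <= hp.interval.start
                and hp.interval.end <= f.interval.end
            ):
                continue
            records.append(
                OverlapRecord(
                    mirna=hp.name,
                    feature=f,
                    orientation=_orientation(hp.interval.strand, f.interval.strand),
                )
            )
    for chrom in sorted(missing_chroms):
        logger.warning("chromosome %s absent from feature set; zero overlaps", chrom)
    records.sort(
        key=lambda r: (
            r.feature.interval.chrom,
            r.feature.interval.start,
            r.mirna,
            r.feature.name,
        )
    )
    return records


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[tuple[int, int]]:
    """Union of closed intervals on one chromosome as (start, end) pairs."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def host_context(
    mirna: MirnaHairpin,
    gene: GenomicFeature,
    exons: Sequence[GenomicFeature],
) -> OverlapRecord:
    """Classify a miRNA inside a host gene.

    context is ``exonic`` when the hairpin lies fully inside the merged
    exon union, ``intronic`` when it shares no base with any exon, and
    ``exon_and_intron`` otherwise.
    """
    if gene.kind != "gene":
        raise ModelError(f"host feature {gene.name!r} is not a gene")
    if not gene.interval.overlaps(mirna.interval):
        raise ModelError(f"gene {gene.name!r} does not overlap miRNA {mirna.name!r}")
    own_exons = [e for e in exons if e.kind == "exon" and e.parent == gene.name]
    union = merge_intervals([e.interval for e in own_exons])
    s, e = mirna.interval.start, mirna.interval.end
    inside = any(us <= s and e <= ue for us, ue in union)
    touches = any(us <= e and s <= ue for us, ue in union)
    if inside:
        context = "exonic"
    elif not touches:
        context = "intronic"
    else:
        context = "exon_and_intron"
    return OverlapRecord(
        mirna=mirna.name,
        feature=gene,
        orientation=_orientation(mirna.interval.strand, gene.interval.strand),
        context=context,
    )


@dataclass
class OverlapSummary:
    """Per-miRNA feature counts plus per-kind totals and maxima."""

    per_mirna: pd.DataFrame  # columns: mirna, kind, count
    totals: dict[str, int]
    top: dict[str, tuple[int, list[str]]]  # kind -> (max count, tied miRNAs)


def summarize_overlaps(records: Sequence[OverlapRecord]) -> OverlapSummary:
    """Count overlaps per miRNA and feature kind; report the maximum-count
    miRNA per kind with ties listed lexicographically."""
    if not records:
        return OverlapSummary(
            per_mirna=pd.DataFrame(columns=["mirna", "kind", "count"]),
            totals={},
            top={},
        )
    df = pd.DataFrame(
        {"mirna": [r.mirna for r in records], "kind": [r.feature.kind for r in records]}
    )
    per = (
        df.groupby(["mirna", "kind"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["kind", "mirna"])
        .reset_index(drop=True)
    )
    totals = df.groupby("kind").size().to_dict()
    top: dict[str, tuple[int, list[str]]] = {}
    for kind, sub in per.groupby("kind"):
        mx = int(sub["count"].max())
        top[kind] = (mx, sorted(sub.loc[sub["count"] == mx, "mirna"]))
    return OverlapSummary(per_mirna=per, totals=totals, top=top)
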