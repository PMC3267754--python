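"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — per-base enumeration, quadratic
double loops, hand-written truth tables — and never calls the interval- or
index-based implementations it is used to check.
"""

from __future__ import annotations

#: all 12 ordered substitutions among RNA bases, classified by hand
TITV_TRUTH_TABLE = {
    ("A", "G"): "transition",
    ("G", "A"): "transition",
    ("C", "U"): "transition",
    ("U", "C"): "transition",
    ("A", "C"): "transversion",
    ("A", "U"): "transversion",
    ("C", "A"): "transversion",
    ("C", "G"): "transversion",
    ("G", "C"): "transversion",
    ("G", "U"): "transversion",
    ("U", "A"): "transversion",
    ("U", "G"): "transversion",
}


def oriented_positions(start: int, end: int, strand: str) -> list[int]:
    """Genomic positions of a span walked 5'->3' along the transcript."""
    positions = list(range(start, end + 1))
    if strand == "-":
        positions.reverse()
    return positions


def brute_force_classify(variant, hairpins) -> list[dict]:
    """Per-base classification of one variant against every hairpin.

    Walks every base of every mature to build an explicit genome->mature
    position map, then checks each affected reference base against it.
    Returns one dict per (hairpin, mature) assignment plus precursor hits.
    """
    results = []
    affected = list(range(variant.interval.start, variant.interval.end + 1))
    for hp in hairpins:
        if hp.interval.chrom != variant.interval.chrom:
            continue
        aff_in = [
            p for p in affected if hp.interval.start <= p <= hp.interval.end
        ]
        if not aff_in:
            continue
        any_mature = False
        for m in hp.matures:
            walk = oriented_positions(
                m.interval.start, m.interval.end, hp.interval.strand
            )
            g2m = {g: i + 1 for i, g in enumerate(walk)}
            mpos = sorted(g2m[p] for p in aff_in if p in g2m)
            if not mpos:
                continue
            any_mature = True
            seed6 = any(2 <= q <= 7 for q in mpos)
            seed7 = any(2 <= q <= 8 for q in mpos)
            results.append(
                {
                    "hairpin": hp.name,
                    "mature": m.name,
                    "region": "seed" if seed7 else "mature_nonseed",
                    "mature_position": mpos[0],
                    "seed6": seed6,
                    "seed7": seed7,
                }
            )
        if not any_mature:
            results.append(
                {
                    "hairpin": hp.name,
                    "mature": None,
                    "region": "precursor",
                    "mature_position": None,
                    "seed6": False,
                    "seed7": False,
                }
            )
    return results


def brute_force_overlaps(hairpins, features) -> set[tuple[str, str]]:
    """Quadratic double loop over all (miRNA, feature) pairs."""
    pairs = set()
    for hp in hairpins:
        for f in features:
            if (
                hp.interval.chrom == f.interval.chrom
                and hp.interval.start <= f.interval.end
                and f.interval.start <= hp.interval.end
            ):
                pairs.add((hp.name, f.name))
    return pairs


def brute_force_host_context(hairpin, gene, exons) -> str:
    """Per-base exon membership over the hairpin span."""
    exon_bases = set()
    for e in exons:
        if e.parent == gene.name:
            exon_bases.update(range(e.interval.start, e.interval.end + 1))
    span = range(hairpin.interval.start, hairpin.interval.end + 1)
    inside = [p in exon_bases for p in span]
    if all(inside):
        return "exonic"
    if not any(inside):
        return "intronic"
    return "exon_and_intron"


def brute_force_seed_sets(hairpins, k: int) -> dict[str, set[str]]:
    """Seed -> mature-name sets built by direct slicing."""
    out: dict[str, set[str]] = {}
    for hp in hairpins:
        for m in hp.matures:
            lo = m.hairpin_offset - 1
            seq = hp.sequence[lo : lo + m.length]
            if len(seq) >= k + 1:
                out.setdefault(seq[1 : k + 1], set()).add(m.name)
    return out


def maximal_adjacent_runs(positions: list[int]) -> list[list[int]]:
    """Maximal runs of consecutive integers (length >= 2)."""
    runs, run = [], []
    for p in sorted(set(positions)) + [None]:
        if run and (p is None or p != run[-1] + 1):
            if len(run) >= 2:
                runs.append(run)
            run = []
        if p is not None:
            run.append(p)
    return runs
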