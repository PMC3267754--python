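"""Synthetic fixture generation with machine-readable ground truth.

The generator emits a complete toy dataset — genome FASTA, miRNA GFF3 and
hairpin FASTA, VCF, QTL/fragile-site BED, host-gene GFF3, and a phenotype
table — together with a ground-truth JSON recording, for every planted
entity, what a correct analysis must recover: per-variant region class and
mature position, Ti/Tv class, DNP run membership, expected seed-switch
hits, feature overlap pairs, host-gene contexts, and planted phenotype
effects.

Ground truth is written by construction and by generator-internal
enumeration over its own sequences (plain double loops and per-base
arithmetic), never by calling the analysis code under test.  Random 6/7mer
seeds collide (4^6 = 4096 keys), so accidental seed sharing is detected
post hoc and recorded rather than forbidden — the truth file stays
truthful.

Fixture genomes are short (tens of kb per chromosome) with i.i.d. uniform
bases outside planted motifs: desk-scale speed with controlled collisions,
no pretense of realistic chromosome lengths or hairpin thermodynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


import numpy as np

from . import io_formats
from .model import (
    GenomicFeature,
    GenomicInterval,
    MatureMir,
    MirnaHairpin,
    ModelError,
    Variant,
)

_DNA = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_DNA2RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}
_RNA2DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}

_TRAIT_GROUPS = [
    "behavior",
    "blood-clinical chemistry",
    "body weight size and growth",
    "immune system",
    "bone",
    "metabolism",
]


@dataclass
class FixtureSpec:
    """Everything the generator needs, with defaults sized for fast tests.

    The phenotype block emulates an inbred-strain panel: 14 strains split
    7/7 between the two seed-SNP genotypes, both sexes, replicated cells,
    an additive genotype effect of ``effect_size`` trait units on the
    effect traits and zero on the null traits, against unit residual noise.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_mirnas: int = 30
    fraction_minus_strand: float = 0.5
    n_seed_snvs: int = 10
    n_mature_snvs: int = 5
    n_precursor_snvs: int = 5
    n_outside_snvs: int = 5
    n_deletions: int = 2
    n_insertions: int = 1
    n_planted_dnps: int = 2
    n_planted_triples: int = 1
    n_planted_seed_switches: int = 3
    n_qtl: int = 10
    n_fragile_sites: int = 5
    n_host_genes: int = 6
    strains_per_genotype: int = 7
    sexes: tuple[str, ...] = ("f", "m")
    n_per_cell: int = 10
    n_effect_traits: int = 3
    n_null_traits: int = 3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    strain_sd: float = 0.0
    sex_effect: float = 0.5

    def validate(self) -> None:
        numeric = {
            k: v
            for k, v in asdict(self).items()
            if isinstance(v, (int, float)) and k != "seed"
        }
        for k, v in numeric.items():
            if v < 0:
                raise ModelError(f"spec field {k} must be >= 0, got {v}")
        if 2 * self.n_planted_seed_switches > self.n_mirnas:
            raise ModelError(
                "planted seed switches need donor and acceptor hairpins: "
                f"{self.n_planted_seed_switches} switches exceed "
                f"{self.n_mirnas} miRNAs / 2"
            )
        if self.n_planted_dnps + self.n_planted_triples > self.n_mirnas:
            raise ModelError("more planted DNP runs than hairpins")
        if self.n_host_genes > self.n_mirnas:
            raise ModelError("more host genes than hairpins to host")
        if not 0 <= self.fraction_minus_strand <= 1:
            raise ModelError("fraction_minus_strand must be in [0, 1]")


@dataclass
class GeneratedFixture:
    """Paths of the emitted files plus the ground-truth dictionary."""

    outdir: Path
    paths: dict[str, Path]
    truth: dict
    hairpins: list[MirnaHairpin] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coordinate helpers on the raw genome (generator-internal, by construction)
# ---------------------------------------------------------------------------


def _hp_to_genome(hp: MirnaHairpin, hpos: int) -> int:
    if hp.interval.strand == "+":
        return hp.interval.start + hpos - 1
    return hp.interval.end - hpos + 1


def _mature_to_genome(m: MatureMir, strand: str, mpos: int) -> int:
    if strand == "+":
        return m.interval.start + mpos - 1
    return m.interval.end - mpos + 1


def _transcript_base(genome: dict[str, list[str]], hp: MirnaHairpin, gpos: int) -> str:
    base = genome[hp.interval.chrom][gpos - 1]
    if hp.interval.strand == "-":
        base = _COMP[base]
    return _DNA2RNA[base]


def _set_transcript_base(
    genome: dict[str, list[str]], hp: MirnaHairpin, gpos: int, rna_base: str
) -> None:
    dna = _RNA2DNA[rna_base]
    if hp.interval.strand == "-":
        dna = _COMP[dna]
    genome[hp.interval.chrom][gpos - 1] = dna


def _hairpin_seq(genome: dict[str, list[str]], hp: MirnaHairpin) -> str:
    chars = genome[hp.interval.chrom][hp.interval.start - 1 : hp.interval.end]
    if hp.interval.strand == "-":
        chars = [_COMP[b] for b in reversed(chars)]
    return "".join(_DNA2RNA[b] for b in chars)


def _titv_dna(ref: str, alt: str) -> str:
    purines = {"A", "G"}
    return "transition" if (ref in purines) == (alt in purines) else "transversion"


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> GeneratedFixture:
    """Generate the full fixture; deterministic under a fixed seed."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome: dict[str, list[str]] = {
        c: [_DNA[i] for i in rng.integers(0, 4, size=spec.chrom_length)]
        for c in chroms
    }

    hairpins = _place_hairpins(spec, rng, chroms)
    vcf_records: list[tuple[str, int, str, str, str]] = []
    truth_variants: list[dict] = []
    used: set[tuple[str, int]] = set()
    snv_positions: dict[str, set[int]] = {}  # hairpin name -> genomic SNV pos
    counter = [1000]

    def next_id() -> str:
        counter[0] += 1
        return f"rs{counter[0]}"

    planted_switches = _plant_seed_switches(
        spec, rng, genome, hairpins, vcf_records, truth_variants, used,
        snv_positions, next_id,
    )
    _plant_dnp_runs(
        spec, rng, genome, hairpins, vcf_records, truth_variants, used,
        snv_positions, next_id,
    )
    _plant_region_snvs(
        spec, rng, genome, hairpins, vcf_records, truth_variants, used,
        snv_positions, next_id,
    )
    _plant_indels(
        spec, rng, genome, hairpins, vcf_records, truth_variants, used, next_id
    )

    # sequences are derived only after all genome edits
    for hp in hairpins:
        hp.sequence = _hairpin_seq(genome, hp)
        hp.validate()

    dnp_runs = _truth_dnp_runs(hairpins, truth_variants)
    expected_switches = _truth_seed_switches(hairpins, truth_variants)
    seed_collisions = _truth_seed_collisions(hairpins)

    features, host_genes, host_truth = _make_features(spec, rng, hairpins, chroms)
    overlap_truth = _truth_overlaps(hairpins, features + [g for g, _ in host_genes])

    pheno_df, pheno_truth = _make_phenotypes(spec, rng)

    truth = {
        "spec": asdict(spec),
        "variants": sorted(
            truth_variants, key=lambda t: (t["chrom"], t["pos"], t["id"])
        ),
        "dnp_runs": dnp_runs,
        "planted_seed_switches": planted_switches,
        "expected_seed_switches": expected_switches,
        "seed_collisions": seed_collisions,
        "overlaps": overlap_truth,
        "host_contexts": host_truth,
        "phenotypes": pheno_truth,
    }

    paths = _write_fixture(
        outdir, chroms, genome, hairpins, vcf_records, features, host_genes,
        pheno_df, truth,
    )
    return GeneratedFixture(outdir=outdir, paths=paths, truth=truth, hairpins=hairpins)


def _place_hairpins(spec, rng, chroms) -> list[MirnaHairpin]:
    strands = ["-"] * round(spec.fraction_minus_strand * spec.n_mirnas)
    strands += ["+"] * (spec.n_mirnas - len(strands))
    rng.shuffle(strands)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    hairpins: list[MirnaHairpin] = []
    margin = 300
    for i in range(spec.n_mirnas):
        length = int(rng.integers(70, 101))
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(margin, spec.chrom_length - length - margin))
            end = start + length - 1
            if all(
                end + margin < s or start - margin > e for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, end))
                break
        else:
            raise ModelError("could not place hairpin without overlap")
        strand = strands[i]
        name = f"syn-mir-{i:03d}"
        hp = MirnaHairpin(
            name=name, interval=GenomicInterval(chrom, start, end, strand)
        )
        # 5p mature near the hairpin 5' end, 3p mature near the 3' end
        o5 = int(rng.integers(2, 7))
        l5 = int(rng.integers(20, 24))
        l3 = int(rng.integers(20, 24))
        tail = int(rng.integers(1, 6))
        o3 = length - tail - l3 + 1
        for suffix, off, ln in (("5p", o5, l5), ("3p", o3, l3)):
            g1 = _hp_to_genome(hp, off)
            g2 = _hp_to_genome(hp, off + ln - 1)
            hp.matures.append(
                MatureMir(
                    name=f"syn-miR-{i:03d}-{suffix}",
                    interval=GenomicInterval(chrom, min(g1, g2), max(g1, g2), strand),
                    hairpin_offset=off,
                    length=ln,
                )
            )
        hairpins.append(hp)
    return hairpins


def _mature_truth(hp, m, mpos_list, titv=None, vclass="snv"):
    seed6 = any(2 <= q <= 7 for q in mpos_list)
    seed7 = any(2 <= q <= 8 for q in mpos_list)
    region = "seed" if seed7 else "mature_nonseed"
    return {
        "hairpin": hp.name,
        "mature": m.name,
        "region": region,
        "mature_position": min(mpos_list),
        "seed6": seed6,
        "seed7": seed7,
        "substitution": titv,
        "vclass": vclass,
    }


def _plant_seed_switches(
    spec, rng, genome, hairpins, vcf_records, truth_variants, used,
    snv_positions, next_id,
):
    """Copy a donor 7mer seed into an acceptor mature, leaving one position
    off by a single substitution; the emitted SNV converts the acceptor
    seed into the donor seed."""
    order = rng.permutation(len(hairpins))
    planted = []
    for i in range(spec.n_planted_seed_switches):
        donor_hp = hairpins[order[2 * i]]
        acceptor_hp = hairpins[order[2 * i + 1]]
        donor = donor_hp.matures[0]
        acceptor = acceptor_hp.matures[0]
        donor_seed7 = "".join(
            _transcript_base(
                genome, donor_hp, _mature_to_genome(donor, donor_hp.interval.strand, q)
            )
            for q in range(2, 9)
        )
        p = int(rng.integers(2, 8))  # position 2..7 switches both 6mer and 7mer
        for q in range(2, 9):
            gpos = _mature_to_genome(acceptor, acceptor_hp.interval.strand, q)
            desired = donor_seed7[q - 2]
            if q == p:
                wrong = [b for b in "ACGU" if b != desired]
                _set_transcript_base(
                    genome, acceptor_hp, gpos,
                    wrong[int(rng.integers(len(wrong)))],
                )
            else:
                _set_transcript_base(genome, acceptor_hp, gpos, desired)
        gpos = _mature_to_genome(acceptor, acceptor_hp.interval.strand, p)
        ref_dna = genome[acceptor_hp.interval.chrom][gpos - 1]
        alt_rna = donor_seed7[p - 2]
        alt_dna = _RNA2DNA[alt_rna]
        if acceptor_hp.interval.strand == "-":
            alt_dna = _COMP[alt_dna]
        vid = next_id()
        chrom = acceptor_hp.interval.chrom
        vcf_records.append((chrom, gpos, vid, ref_dna, alt_dna))
        used.add((chrom, gpos))
        snv_positions.setdefault(acceptor_hp.name, set()).add(gpos)
        truth_variants.append(
            {
                "id": vid,
                "chrom": chrom,
                "pos": gpos,
                "ref": ref_dna,
                "alt": alt_dna,
                **_mature_truth(
                    acceptor_hp, acceptor, [p], _titv_dna(ref_dna, alt_dna)
                ),
            }
        )
        planted.append(
            {
                "variant_id": vid,
                "source_mature": acceptor.name,
                "donor_mature": donor.name,
                "mature_position": p,
                "donor_seed7": donor_seed7,
            }
        )
    return planted


def _free_precursor_positions(hp) -> list[int]:
    """Genomic positions inside the hairpin but outside every mature."""
    inside = set(range(hp.interval.start, hp.interval.end + 1))
    for m in hp.matures:
        inside -= set(range(m.interval.start, m.interval.end + 1))
    return sorted(inside)


def _plant_dnp_runs(
    spec, rng, genome, hairpins, vcf_records, truth_variants, used,
    snv_positions, next_id,
):
    """Adjacent-SNV runs (length 2 and 3) planted in precursor regions."""
    runs = [2] * spec.n_planted_dnps + [3] * spec.n_planted_triples
    candidates = rng.permutation(len(hairpins))
    ci = 0
    for run_len in runs:
        while True:
            hp = hairpins[candidates[ci % len(candidates)]]
            ci += 1
            free = _free_precursor_positions(hp)
            starts = [
                p
                for p in free
                if all(p + d in free for d in range(run_len))
                and all(
                    (hp.interval.chrom, p + d) not in used
                    for d in range(-1, run_len + 1)
                )
            ]
            if starts:
                break
        start = starts[int(rng.integers(len(starts)))]
        chrom = hp.interval.chrom
        for d in range(run_len):
            gpos = start + d
            ref_dna = genome[chrom][gpos - 1]
            alt_dna = [b for b in _DNA if b != ref_dna][int(rng.integers(3))]
            vid = next_id()
            vcf_records.append((chrom, gpos, vid, ref_dna, alt_dna))
            used.add((chrom, gpos))
            snv_positions.setdefault(hp.name, set()).add(gpos)
            truth_variants.append(
                {
                    "id": vid,
                    "chrom": chrom,
                    "pos": gpos,
                    "ref": ref_dna,
                    "alt": alt_dna,
                    "hairpin": hp.name,
                    "mature": None,
                    "region": "precursor",
                    "mature_position": None,
                    "seed6": False,
                    "seed7": False,
                    "substitution": _titv_dna(ref_dna, alt_dna),
                    "vclass": "snv",
                }
            )


def _plant_region_snvs(
    spec, rng, genome, hairpins, vcf_records, truth_variants, used,
    snv_positions, next_id,
):
    all_hp_spans: dict[str, list[tuple[int, int]]] = {}
    for hp in hairpins:
        all_hp_spans.setdefault(hp.interval.chrom, []).append(
            (hp.interval.start, hp.interval.end)
        )

    def emit_snv(hp, gpos, truth_extra):
        chrom = hp.interval.chrom if hp else truth_extra["chrom"]
        ref_dna = genome[chrom][gpos - 1]
        alt_dna = [b for b in _DNA if b != ref_dna][int(rng.integers(3))]
        vid = next_id()
        vcf_records.append((chrom, gpos, vid, ref_dna, alt_dna))
        used.add((chrom, gpos))
        if hp is not None:
            snv_positions.setdefault(hp.name, set()).add(gpos)
        rec = {
            "id": vid,
            "chrom": chrom,
            "pos": gpos,
            "ref": ref_dna,
            "alt": alt_dna,
            "vclass": "snv",
        }
        rec.update({k: v for k, v in truth_extra.items() if k != "chrom"})
        rec["substitution"] = _titv_dna(ref_dna, alt_dna)
        truth_variants.append(rec)

    def clear(hp, gpos):
        """Avoid duplicate positions and accidental adjacency runs."""
        chrom = hp.interval.chrom
        taken = snv_positions.get(hp.name, set())
        return (
            (chrom, gpos) not in used
            and gpos - 1 not in taken
            and gpos + 1 not in taken
        )

    hp_idx = rng.permutation(len(hairpins))
    # seed SNVs: mature positions 2..8
    for i in range(spec.n_seed_snvs):
        for attempt in range(200):
            hp = hairpins[hp_idx[(i + attempt) % len(hairpins)]]
            m = hp.matures[int(rng.integers(len(hp.matures)))]
            q = int(rng.integers(2, 9))
            gpos = _mature_to_genome(m, hp.interval.strand, q)
            if clear(hp, gpos):
                break
        emit_snv(hp, gpos, _mature_truth(hp, m, [q]))
    # mature non-seed SNVs: position 1 or 9..length
    for i in range(spec.n_mature_snvs):
        for attempt in range(200):
            hp = hairpins[hp_idx[(i + attempt + 7) % len(hairpins)]]
            m = hp.matures[int(rng.integers(len(hp.matures)))]
            q = 1 if rng.random() < 0.3 else int(rng.integers(9, m.length + 1))
            gpos = _mature_to_genome(m, hp.interval.strand, q)
            if clear(hp, gpos):
                break
        emit_snv(hp, gpos, _mature_truth(hp, m, [q]))
    # precursor SNVs: inside the hairpin, outside every mature
    for i in range(spec.n_precursor_snvs):
        for attempt in range(200):
            hp = hairpins[hp_idx[(i + attempt + 13) % len(hairpins)]]
            free = [p for p in _free_precursor_positions(hp) if clear(hp, p)]
            if free:
                gpos = free[int(rng.integers(len(free)))]
                break
        emit_snv(
            hp,
            gpos,
            {
                "hairpin": hp.name,
                "mature": None,
                "region": "precursor",
                "mature_position": None,
                "seed6": False,
                "seed7": False,
            },
        )
    # intergenic SNVs
    for _ in range(spec.n_outside_snvs):
        while True:
            chrom = f"chr{int(rng.integers(spec.n_chromosomes)) + 1}"
            gpos = int(rng.integers(1, spec.chrom_length + 1))
            in_hp = any(
                s <= gpos <= e for s, e in all_hp_spans.get(chrom, [])
            )
            if not in_hp and (chrom, gpos) not in used:
                break
        ref_dna = genome[chrom][gpos - 1]
        alt_dna = [b for b in _DNA if b != ref_dna][int(rng.integers(3))]
        vid = next_id()
        vcf_records.append((chrom, gpos, vid, ref_dna, alt_dna))
        used.add((chrom, gpos))
        truth_variants.append(
            {
                "id": vid,
                "chrom": chrom,
                "pos": gpos,
                "ref": ref_dna,
                "alt": alt_dna,
                "hairpin": None,
                "mature": None,
                "region": "outside",
                "mature_position": None,
                "seed6": False,
                "seed7": False,
                "substitution": _titv_dna(ref_dna, alt_dna),
                "vclass": "snv",
            }
        )


def _plant_indels(
    spec, rng, genome, hairpins, vcf_records, truth_variants, used, next_id
):
    """Deletions spanning the seed 3' boundary and insertions inside the
    seed, anchored VCF-style on the preceding base."""
    hp_idx = list(rng.permutation(len(hairpins)))
    for i in range(spec.n_deletions):
        for attempt in range(200):
            hp = hairpins[hp_idx[(3 * i + attempt) % len(hairpins)]]
            m = hp.matures[0]
            q0 = int(rng.integers(6, 9))  # deletion of mature positions q0..q0+2
            gp = sorted(
                _mature_to_genome(m, hp.interval.strand, q) for q in (q0, q0 + 2)
            )
            anchor = gp[0] - 1
            if anchor >= 1 and all(
                (hp.interval.chrom, p) not in used
                for p in range(anchor, gp[1] + 1)
            ):
                break
        chrom = hp.interval.chrom
        ref = "".join(genome[chrom][anchor - 1 : gp[1]])
        alt = ref[0]
        vid = next_id()
        vcf_records.append((chrom, anchor, vid, ref, alt))
        for p in range(anchor, gp[1] + 1):
            used.add((chrom, p))
        mpos = [q0, q0 + 1, q0 + 2]
        rec = {
            "id": vid,
            "chrom": chrom,
            "pos": anchor,
            "ref": ref,
            "alt": alt,
            **_mature_truth(hp, m, mpos, None, "deletion"),
        }
        truth_variants.append(rec)
    for i in range(spec.n_insertions):
        for attempt in range(200):
            hp = hairpins[hp_idx[(5 * i + attempt + 1) % len(hairpins)]]
            m = hp.matures[-1]
            q0 = int(rng.integers(3, 7))  # insertion between positions q0, q0+1
            gp = sorted(
                _mature_to_genome(m, hp.interval.strand, q) for q in (q0, q0 + 1)
            )
            if all((hp.interval.chrom, p) not in used for p in gp):
                break
        chrom = hp.interval.chrom
        anchor = gp[0]
        ref = genome[chrom][anchor - 1]
        ins = "".join(_DNA[j] for j in rng.integers(0, 4, size=2))
        vid = next_id()
        vcf_records.append((chrom, anchor, vid, ref, ref + ins))
        used.add((chrom, anchor))
        used.add((chrom, anchor + 1))
        # affected reference bases: the two flanking the insertion point
        mflank = sorted(q for q in (q0, q0 + 1))
        rec = {
            "id": vid,
            "chrom": chrom,
            "pos": anchor,
            "ref": ref,
            "alt": ref + ins,
            **_mature_truth(hp, m, mflank, None, "insertion"),
        }
        truth_variants.append(rec)


def _truth_dnp_runs(hairpins, truth_variants) -> list[dict]:
    """Maximal runs of genomically adjacent SNVs per hairpin (post hoc, so
    accidental adjacencies are recorded truthfully)."""
    by_hp: dict[str, dict[int, str]] = {}
    for t in truth_variants:
        if t["vclass"] == "snv" and t.get("hairpin"):
            by_hp.setdefault(t["hairpin"], {})[t["pos"]] = t["id"]
    runs = []
    for hp_name in sorted(by_hp):
        positions = sorted(by_hp[hp_name])
        run: list[int] = []
        for pos in positions + [None]:
            if run and (pos is None or pos != run[-1] + 1):
                if len(run) >= 2:
                    runs.append(
                        {
                            "hairpin": hp_name,
                            "positions": run[:],
                            "ids": [by_hp[hp_name][p] for p in run],
                            "length": len(run),
                        }
                    )
                run = []
            if pos is not None:
                run.append(pos)
    return runs


def _truth_seed_switches(hairpins, truth_variants) -> list[dict]:
    """Expected seed-switch hits by brute-force enumeration: apply every
    seed SNV to its mature and compare the mutant seed against every
    annotated mature's seed directly."""
    seqs = {}
    for hp in hairpins:
        for m in hp.matures:
            seqs[m.name] = (_hairpin_seq_cached(hp), m.hairpin_offset, m.length)
    mature_seq = {
        name: s[o - 1 : o - 1 + ln] for name, (s, o, ln) in seqs.items()
    }
    expected = []
    for t in truth_variants:
        if t["vclass"] != "snv" or t["region"] != "seed" or not t.get("mature"):
            continue
        hp = next(h for h in hairpins if h.name == t["hairpin"])
        ref_rna = _DNA2RNA[t["ref"] if hp.interval.strand == "+" else _COMP[t["ref"]]]
        alt_rna = _DNA2RNA[t["alt"] if hp.interval.strand == "+" else _COMP[t["alt"]]]
        seq = mature_seq[t["mature"]]
        p = t["mature_position"]
        assert seq[p - 1] == ref_rna
        mutant = seq[: p - 1] + alt_rna + seq[p:]
        for k in (6, 7):
            if len(seq) < k + 1:
                continue
            wt, mut = seq[1 : k + 1], mutant[1 : k + 1]
            if wt == mut:
                continue
            matched = sorted(
                name
                for name, other in mature_seq.items()
                if name != t["mature"]
                and len(other) >= k + 1
                and other[1 : k + 1] == mut
            )
            if matched:
                expected.append(
                    {
                        "variant_id": t["id"],
                        "source_mature": t["mature"],
                        "k": k,
                        "mutant_seed": mut,
                        "matched": matched,
                    }
                )
    expected.sort(key=lambda e: (e["variant_id"], e["source_mature"], e["k"]))
    return expected


def _hairpin_seq_cached(hp: MirnaHairpin) -> str:
    if hp.sequence is None:
        raise ModelError("hairpin sequence not yet derived")
    return hp.sequence


def _truth_seed_collisions(hairpins) -> dict[str, dict[str, list[str]]]:
    out: dict[str, dict[str, list[str]]] = {}
    for k in (6, 7):
        seen: dict[str, list[str]] = {}
        for hp in hairpins:
            for m in hp.matures:
                seq = hp.sequence[m.hairpin_offset - 1 : m.hairpin_offset - 1 + m.length]
                if len(seq) >= k + 1:
                    seen.setdefault(seq[1 : k + 1], []).append(m.name)
        out[str(k)] = {
            s: sorted(names) for s, names in sorted(seen.items()) if len(names) > 1
        }
    return out


def _make_features(spec, rng, hairpins, chroms):
    features: list[GenomicFeature] = []
    for kind, count, prefix, lo, hi in (
        ("qtl", spec.n_qtl, "qtl", 2000, 8000),
        ("fragile_site", spec.n_fragile_sites, "fra", 1000, 5000),
    ):
        for i in range(count):
            length = int(rng.integers(lo, hi))
            if i < count // 2 and hairpins:
                hp = hairpins[int(rng.integers(len(hairpins)))]
                chrom = hp.interval.chrom
                start = max(1, hp.interval.start - int(rng.integers(0, length // 2)))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(1, spec.chrom_length - length))
            end = min(start + length - 1, spec.chrom_length)
            features.append(
                GenomicFeature(
                    interval=GenomicInterval(chrom, start, end, "."),
                    kind=kind,
                    name=f"{prefix}_{i:03d}",
                )
            )

    host_genes: list[tuple[GenomicFeature, list[GenomicFeature]]] = []
    host_truth: list[dict] = []
    hp_order = rng.permutation(len(hairpins))
    for i in range(spec.n_host_genes):
        hp = hairpins[hp_order[i]]
        pad5 = int(rng.integers(500, 2000))
        pad3 = int(rng.integers(500, 2000))
        gstart = max(1, hp.interval.start - pad5)
        gend = min(spec.chrom_length, hp.interval.end + pad3)
        sense = i % 2 == 0
        gstrand = hp.interval.strand if sense else ("-" if hp.interval.strand == "+" else "+")
        gname = f"gene_{i:03d}"
        gene = GenomicFeature(
            interval=GenomicInterval(hp.interval.chrom, gstart, gend, gstrand),
            kind="gene",
            name=gname,
        )
        case = i % 3
        exons = []
        if case == 0:  # exonic: one exon covering the hairpin
            es = max(gstart, hp.interval.start - int(rng.integers(10, 50)))
            ee = min(gend, hp.interval.end + int(rng.integers(10, 50)))
            exons.append((es, ee))
            context = "exonic"
        elif case == 1:  # intronic: exons flank the hairpin without touching it
            exons.append((gstart, max(gstart + 1, hp.interval.start - 50)))
            exons.append((min(gend - 1, hp.interval.end + 50), gend))
            context = "intronic"
        else:  # exon boundary inside the hairpin
            mid = hp.interval.start + len(hp.interval) // 3
            exons.append((gstart, mid))
            context = "exon_and_intron"
        exon_feats = [
            GenomicFeature(
                interval=GenomicInterval(hp.interval.chrom, es, ee, gstrand),
                kind="exon",
                name=f"{gname}_e{j + 1}",
                parent=gname,
            )
            for j, (es, ee) in enumerate(exons)
        ]
        host_genes.append((gene, exon_feats))
        host_truth.append(
            {
                "mirna": hp.name,
                "gene": gname,
                "orientation": "sense" if sense else "antisense",
                "context": context,
            }
        )
    host_truth.sort(key=lambda h: (h["gene"], h["mirna"]))
    return features, host_genes, host_truth


def _truth_overlaps(hairpins, features) -> list[dict]:
    """Quadratic double loop over every (miRNA, feature) pair."""
    out = []
    for hp in hairpins:
        for f in features:
            if (
                hp.interval.chrom == f.interval.chrom
                and hp.interval.start <= f.interval.end
                and f.interval.start <= hp.interval.end
            ):
                out.append(
                    {"mirna": hp.name, "feature": f.name, "kind": f.kind}
                )
    out.sort(key=lambda o: (o["kind"], o["feature"], o["mirna"]))
    return out


def _make_phenotypes(spec, rng):
    import pandas as pd

    n_strains = 2 * spec.strains_per_genotype
    strains = [f"S{i + 1:02d}" for i in range(n_strains)]
    genotype = {
        s: ("CC" if i < spec.strains_per_genotype else "TT")
        for i, s in enumerate(strains)
    }
    rows = []
    pheno_truth = []
    traits = [("eff", spec.effect_size, i) for i in range(spec.n_effect_traits)]
    traits += [("null", 0.0, i) for i in range(spec.n_null_traits)]
    for kind, delta, i in traits:
        tname = f"trait_{kind}_{i:02d}"
        group = _TRAIT_GROUPS[(i + (0 if kind == "eff" else 3)) % len(_TRAIT_GROUPS)]
        strain_eff = {s: rng.normal(0, spec.strain_sd) for s in strains}
        for s in strains:
            g = genotype[s]
            gterm = delta / 2 if g == "TT" else -delta / 2
            for sex in spec.sexes:
                sterm = spec.sex_effect / 2 if sex == "m" else -spec.sex_effect / 2
                vals = 10.0 + gterm + strain_eff[s] + sterm + rng.normal(
                    0, spec.noise_sd, size=spec.n_per_cell
                )
                for v in vals:
                    rows.append(
                        {
                            "strain": s,
                            "sex": sex,
                            "genotype": g,
                            "trait": tname,
                            "group": group,
                            "value": float(v),
                        }
                    )
        pheno_truth.append(
            {"trait": tname, "group": group, "effect_size": delta}
        )
    return pd.DataFrame(rows), pheno_truth


def _write_fixture(
    outdir, chroms, genome, hairpins, vcf_records, features, host_genes,
    pheno_df, truth,
):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    paths = {
        "mirna_gff": outdir / "mirna.gff3",
        "hairpin_fasta": outdir / "hairpins.fa",
        "genome_fasta": outdir / "genome.fa",
        "vcf": outdir / "variants.vcf",
        "qtl_bed": outdir / "qtl.bed",
        "fragile_bed": outdir / "fragile_sites.bed",
        "gene_gff": outdir / "genes.gff3",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "ground_truth.json",
    }
    io_formats.write_mirna_gff(hairpins, paths["mirna_gff"])
    io_formats.write_hairpin_fasta(
        {hp.name: hp.sequence for hp in hairpins}, paths["hairpin_fasta"]
    )
    seqio_write(
        [
            SeqRecord(Seq("".join(genome[c])), id=c, description="")
            for c in chroms
        ],
        str(paths["genome_fasta"]),
        "fasta",
    )
    io_formats.write_vcf(
        vcf_records, {c: len(genome[c]) for c in chroms}, paths["vcf"]
    )
    io_formats.write_bed(
        [f for f in features if f.kind == "qtl"], paths["qtl_bed"]
    )
    io_formats.write_bed(
        [f for f in features if f.kind == "fragile_site"], paths["fragile_bed"]
    )
    gene_feats = [g for g, _ in host_genes] + [
        e for _, exons in host_genes for e in exons
    ]
    io_formats.write_gene_gff(gene_feats, paths["gene_gff"])
    io_formats.write_phenotypes(pheno_df, paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# strand-mirror transform (for strand-symmetry checks)
# ---------------------------------------------------------------------------


def mirror_hairpins(
    hairpins: list[MirnaHairpin], chrom_lengths: dict[str, int]
) -> list[MirnaHairpin]:
    """Model after reverse-complementing every chromosome: coordinates are
    mirrored and strands flipped, while transcript-frame quantities
    (sequences, hairpin offsets) are untouched."""
    out = []
    for hp in hairpins:
        L = chrom_lengths[hp.interval.chrom]
        flip = "-" if hp.interval.strand == "+" else "+"
        nhp = MirnaHairpin(
            name=hp.name,
            interval=GenomicInterval(
                hp.interval.chrom, L - hp.interval.end + 1, L - hp.interval.start + 1, flip
            ),
            sequence=hp.sequence,
        )
        for m in hp.matures:
            nhp.matures.append(
                MatureMir(
                    name=m.name,
                    interval=GenomicInterval(
                        m.interval.chrom,
                        L - m.interval.end + 1,
                        L - m.interval.start + 1,
                        flip,
                    ),
                    hairpin_offset=m.hairpin_offset,
                    length=m.length,
                )
            )
        nhp.validate()
        out.append(nhp)
    return out


def mirror_variants(
    variants: list[Variant], chrom_lengths: dict[str, int]
) -> list[Variant]:
    """Variants after reverse-complementing every chromosome: positions
    mirrored, alleles reverse-complemented (they live on the + strand)."""
    from Bio.Seq import reverse_complement

    out = []
    for v in variants:
        L = chrom_lengths[v.interval.chrom]
        out.append(
            Variant(
                id=v.id,
                interval=GenomicInterval(
                    v.interval.chrom,
                    L - v.interval.end + 1,
                    L - v.interval.start + 1,
                    ".",
                ),
                ref=str(reverse_complement(v.ref)) if v.ref else "",
                alt=str(reverse_complement(v.alt)) if v.alt else "",
            )
        )
    return out


# ---------------------------------------------------------------------------
# canonical worked example: the miR-96 -> miR-514 seed switch
# ---------------------------------------------------------------------------

#: hairpin modeled on the published miR-96 precursor; the mature starts at
#: hairpin position 9, so mature position 5 is precursor position +13.
MIR96_LIKE_HAIRPIN = (
    "UGGCCGAUUUUGGCACUAGCACAUUUUUGCU"
    "UGUGUCUCUCCGCUCUGAGCAAUCAUGUGCAGUGCCAAUAUGGGAAA"
)
MIR96_LIKE_MATURE = "UUUGGCACUAGCACAUUUUUGCU"

#: mature modeled on published miR-514 (seed UUGACAC), embedded in a
#: synthetic hairpin context.
MIR514_LIKE_MATURE = "AUUGACACUUCUGUGAGUAGA"
MIR514_LIKE_HAIRPIN = (
    "GCGGGUGC" + MIR514_LIKE_MATURE + "GUAAUUCUCACAGAGUGUCAAUGCUGUGCC"
)


def mir96_like_fixture(outdir: str | Path) -> GeneratedFixture:
    """Two-miRNA fixture reproducing the miR-96 -> miR-514 seed switch.

    The miR-96-like hairpin sits on the minus strand (as the real gene
    does) at its published span; the single VCF variant is the mature
    position-5 G>A substitution (precursor +13) written as C>T on the
    plus strand.  Mature sequences are the published ones; the miR-514-like
    hairpin context is synthetic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    start96, end96 = 129414532, 129414532 + len(MIR96_LIKE_HAIRPIN) - 1
    hp96 = MirnaHairpin(
        name="mir-96-like",
        interval=GenomicInterval("chr7", start96, end96, "-"),
        sequence=MIR96_LIKE_HAIRPIN,
    )
    off96 = MIR96_LIKE_HAIRPIN.index(MIR96_LIKE_MATURE) + 1
    m_end = end96 - off96 + 1
    hp96.matures.append(
        MatureMir(
            name="miR-96-like",
            interval=GenomicInterval(
                "chr7", m_end - len(MIR96_LIKE_MATURE) + 1, m_end, "-"
            ),
            hairpin_offset=off96,
            length=len(MIR96_LIKE_MATURE),
        )
    )
    hp96.validate()

    start514 = 1_000_001
    end514 = start514 + len(MIR514_LIKE_HAIRPIN) - 1
    hp514 = MirnaHairpin(
        name="mir-514-like",
        interval=GenomicInterval("chrX", start514, end514, "+"),
        sequence=MIR514_LIKE_HAIRPIN,
    )
    off514 = MIR514_LIKE_HAIRPIN.index(MIR514_LIKE_MATURE) + 1
    hp514.matures.append(
        MatureMir(
            name="miR-514-like",
            interval=GenomicInterval(
                "chrX",
                start514 + off514 - 1,
                start514 + off514 - 1 + len(MIR514_LIKE_MATURE) - 1,
                "+",
            ),
            hairpin_offset=off514,
            length=len(MIR514_LIKE_MATURE),
        )
    )
    hp514.validate()

    hairpins = [hp96, hp514]
    # mature position 5 on the minus strand: genomic = mature.end - 5 + 1
    gpos = hp96.matures[0].interval.end - 5 + 1
    vcf_records = [("chr7", gpos, "var_mir96_plus13", "C", "T")]

    paths = {
        "mirna_gff": outdir / "mir96_like.gff3",
        "hairpin_fasta": outdir / "mir96_like.fa",
        "vcf": outdir / "mir96_like.vcf",
    }
    io_formats.write_mirna_gff(hairpins, paths["mirna_gff"])
    io_formats.write_hairpin_fasta(
        {hp.name: hp.sequence for hp in hairpins}, paths["hairpin_fasta"]
    )
    io_formats.write_vcf(
        vcf_records, {"chr7": 130_000_000, "chrX": 2_000_000}, paths["vcf"]
    )
    truth = {
        "expected_hit": {
            "variant_id": "var_mir96_plus13",
            "source_mature": "miR-96-like",
            "matched": ["miR-514-like"],
        }
    }
    return GeneratedFixture(outdir=outdir, paths=paths, truth=truth, hairpins=hairpins)
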