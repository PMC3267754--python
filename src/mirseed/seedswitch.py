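"""Seed-switch detection.

A seed variant can convert one miRNA's seed into the seed of a different
annotated miRNA (the classic example being a mature-position-5 G>A in
miR-96 whose mutant seed perfectly matches miR-514), potentially
redirecting the whole target repertoire.  Detection is exact string
matching of the mutant seed against an index of all annotated seeds, for
both the 6mer (positions 2-7) and 7mer (positions 2-8) definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .annotator import AnnotatedVariant
from .model import (
    MirnaHairpin,
    ModelError,
    REGION_SEED,
    extract_seed,
    mature_sequence,
)


@dataclass
class SeedIndex:
    """Exact-match lookup from a k-mer seed string to the mature miRNAs
    carrying it.  Matures sharing a seed (seed families) share a key."""

    k: int
    lookup: dict[str, set[str]] = field(default_factory=dict)

    def add(self, seed: str, mature_name: str) -> None:
        self.lookup.setdefault(seed, set()).add(mature_name)

    def matches(self, seed: str) -> set[str]:
        return set(self.lookup.get(seed, ()))


@dataclass(frozen=True)
class SeedSwitchHit:
    """One variant whose mutant seed equals another annotated miRNA's seed."""

    source_mature: str
    variant_id: str
    k: int
    wildtype_seed: str
    mutant_seed: str
    matched_matures: frozenset[str]

    def __post_init__(self) -> None:
        if not self.matched_matures:
            raise ModelError("seed-switch hit with empty match set")
        if self.source_mature in self.matched_matures:
            raise ModelError("seed-switch hit must exclude its source mature")


def build_seed_index(mirnas: Sequence[MirnaHairpin], k: int) -> SeedIndex:
    """Index the k-mer seeds of every mature long enough to carry one."""
    index = SeedIndex(k=k)
    for hp in mirnas:
        for m in hp.matures:
            if m.length >= k + 1:
                index.add(extract_seed(mature_sequence(hp, m), k), m.name)
    return index


def mature_sequences(mirnas: Iterable[MirnaHairpin]) -> dict[str, str]:
    """Mapping mature name -> 5'->3' sequence, for all matures."""
    return {
        m.name: mature_sequence(hp, m) for hp in mirnas for m in hp.matures
    }


def apply_variant_to_mature(
    mature_seq: str, mature_position: int, ref_rna: str, alt_rna: str
) -> str:
    """Apply a substitution (SNV or MNP) at a 1-based mature position.

    ``ref_rna``/``alt_rna`` are transcript-oriented, so the replacement is a
    straight splice; the reference allele must match the mature sequence.
    """
    if len(ref_rna) != len(alt_rna) or not ref_rna:
        raise ModelError("only length-preserving substitutions can be applied")
    lo = mature_position - 1
    hi = lo + len(ref_rna)
    if lo < 0 or hi > len(mature_seq):
        raise ModelError(
            f"substitution at position {mature_position} (+{len(ref_rna)} nt) "
            f"exceeds mature of length {len(mature_seq)}"
        )
    observed = mature_seq[lo:hi]
    if observed != ref_rna:
        raise ModelError(
            f"reference allele {ref_rna!r} does not match mature sequence "
            f"{observed!r} at position {mature_position}"
        )
    return mature_seq[:lo] + alt_rna + mature_seq[hi:]


def find_seed_switches(
    annotated: Sequence[AnnotatedVariant],
    index6: SeedIndex,
    index7: SeedIndex,
    mature_seqs: dict[str, str],
) -> list[SeedSwitchHit]:
    """Screen seed variants for mutant seeds matching other miRNAs.

    Only substitutions (SNV/MNP) in the seed region are considered.  For
    each k the variant must actually change that k-mer (a variant at mature
    position 8 can only produce a 7mer switch); self-matches are excluded.
    """
    hits: list[SeedSwitchHit] = []
    seen: set[tuple] = set()
    for a in annotated:
        if a.region != REGION_SEED or a.mature is None or a.ref_mismatch:
            continue
        if a.variant.vclass not in ("snv", "mnp"):
            continue
        seq = mature_seqs.get(a.mature)
        if seq is None or a.mature_position is None:
            continue
        if a.mature_position - 1 + len(a.ref_rna) > len(seq):
            continue  # substitution runs off the mature 3' end
        mutant = apply_variant_to_mature(
            seq, a.mature_position, a.ref_rna, a.alt_rna
        )
        for k, index in ((6, index6), (7, index7)):
            if len(seq) < k + 1:
                continue
            wt_seed = extract_seed(seq, k)
            mut_seed = extract_seed(mutant, k)
            if mut_seed == wt_seed:
                continue  # this k-mer is untouched (or restored) by the variant
            matched = index.matches(mut_seed) - {a.mature}
            if not matched:
                continue
            key = (a.variant.id, a.mature, k, mut_seed)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                SeedSwitchHit(
                    source_mature=a.mature,
                    variant_id=a.variant.id,
                    k=k,
                    wildtype_seed=wt_seed,
                    mutant_seed=mut_seed,
                    matched_matures=frozenset(matched),
                )
            )
    hits.sort(key=lambda h: (h.variant_id, h.source_mature, h.k))
    return hits
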