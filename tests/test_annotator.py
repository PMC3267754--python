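"""Region classification, Ti/Tv typing, and DNP merging."""

from __future__ import annotations

import random

import pytest

from mirseed.annotator import (
    annotate,
    classify_region,
    classify_substitution,
    merge_dnps,
    titv_counts,
)
from mirseed.model import (
    GenomicInterval,
    MatureMir,
    MirnaHairpin,
    ModelError,
    Variant,
    complement_rna,
)

from _oracles import TITV_TRUTH_TABLE, brute_force_classify, maximal_adjacent_runs


def _simple_hairpin(strand="+"):
    seq = "AACGUACGUACGUACGUACGUACGUACGUACGUACGUACG"  # 40 nt
    hp = MirnaHairpin(
        name="mir-s",
        interval=GenomicInterval("chr1", 1001, 1040, strand),
        sequence=seq,
    )
    off, ln = 5, 22
    if strand == "+":
        ms, me = 1001 + off - 1, 1001 + off - 1 + ln - 1
    else:
        me = 1040 - off + 1
        ms = me - ln + 1
    hp.matures.append(
        MatureMir(
            name="miR-s",
            interval=GenomicInterval("chr1", ms, me, strand),
            hairpin_offset=off,
            length=ln,
        )
    )
    hp.validate()
    return hp


def _snv(pos, ref="A", alt="G", vid="v1"):
    return Variant(
        id=vid, interval=GenomicInterval("chr1", pos, pos, "."), ref=ref, alt=alt
    )


class TestClassifySubstitution:
    def test_truth_table_exhaustive(self):
        """All 12 ordered pairs: 4 transitions, 8 transversions."""
        results = {
            (r, a): classify_substitution(r, a) for (r, a) in TITV_TRUTH_TABLE
        }
        assert results == TITV_TRUTH_TABLE
        assert sum(v == "transition" for v in results.values()) == 4
        assert sum(v == "transversion" for v in results.values()) == 8

    def test_complement_invariance(self):
        for (r, a), cls in TITV_TRUTH_TABLE.items():
            assert classify_substitution(complement_rna(r), complement_rna(a)) == cls

    def test_identical_or_invalid_rejected(self):
        with pytest.raises(ModelError):
            classify_substitution("A", "A")
        with pytest.raises(ModelError):
            classify_substitution("A", "T")  # DNA base in RNA context


class TestClassifyRegion:
    def test_seed_positions(self):
        hp = _simple_hairpin()
        mat = hp.matures[0]
        # mature position 4 -> seed
        (a,) = classify_region(_snv(mat.interval.start + 3, ref="U"), hp)
        assert a.region == "seed" and a.mature_position == 4
        assert a.seed6_member and a.seed7_member

    def test_position_one_not_seed(self):
        hp = _simple_hairpin()
        mat = hp.matures[0]
        (a,) = classify_region(_snv(mat.interval.start, ref="U"), hp)
        assert a.region == "mature_nonseed" and a.mature_position == 1

    def test_position_eight_is_seed7_only(self):
        hp = _simple_hairpin()
        mat = hp.matures[0]
        (a,) = classify_region(_snv(mat.interval.start + 7), hp)
        assert a.region == "seed"
        assert a.seed7_member and not a.seed6_member

    def test_precursor(self):
        hp = _simple_hairpin()
        (a,) = classify_region(_snv(hp.interval.start), hp)
        assert a.region == "precursor" and a.mature is None

    def test_deletion_spanning_seed_boundary(self):
        """A 3-bp deletion over mature positions 7-9 touches seed bases."""
        hp = _simple_hairpin()
        mat = hp.matures[0]
        start = mat.interval.start + 6  # mature position 7
        v = Variant(
            id="del1",
            interval=GenomicInterval("chr1", start, start + 2, "."),
            ref="CGT",
            alt="",
        )
        (a,) = classify_region(v, hp)
        assert a.region == "seed"
        assert a.mature_position == 7
        assert a.seed6_member and a.seed7_member

    def test_minus_strand_ref_rna_is_complement(self):
        hp = _simple_hairpin(strand="-")
        mat = hp.matures[0]
        # mature position 3 on minus strand
        gpos = mat.interval.end - 2
        v = _snv(gpos, ref="G", alt="A")
        (a,) = classify_region(v, hp)
        assert a.ref_rna == "C" and a.alt_rna == "U"
        assert a.substitution == "transition"

    def test_ref_mismatch_flagged_not_dropped(self):
        hp = _simple_hairpin()
        v = _snv(hp.interval.start, ref="G", alt="C")  # hairpin base is A
        (a,) = classify_region(v, hp)
        assert a.ref_mismatch


class TestAnnotate:
    def test_constructed_three_variant_fixture(self):
        hp = _simple_hairpin()
        mat = hp.matures[0]
        vs = [
            _snv(mat.interval.start + 3, ref="U", vid="seed1"),
            _snv(hp.interval.start + 1, ref="A", vid="prec1"),
            _snv(5000, vid="far1"),
        ]
        ann = annotate(vs, [hp])
        assert {a.variant.id: a.region for a in ann} == {
            "seed1": "seed",
            "prec1": "precursor",
        }
        ann_all = annotate(vs, [hp], include_outside=True)
        assert {a.variant.id: a.region for a in ann_all}["far1"] == "outside"

    def test_matches_brute_force_oracle_random(self, small_model):
        _, hairpins, variants = small_model
        got = annotate(variants, hairpins)
        expected = []
        for v in variants:
            for r in brute_force_classify(v, hairpins):
                expected.append(
                    (v.id, r["hairpin"], r["mature"], r["region"], r["mature_position"])
                )
        produced = [
            (a.variant.id, a.hairpin, a.mature, a.region, a.mature_position)
            for a in got
        ]
        assert sorted(produced) == sorted(expected)

    def test_titv_sum_equals_snv_count(self, small_model):
        _, hairpins, variants = small_model
        ann = annotate(variants, hairpins, include_outside=True)
        ti, tv = titv_counts(ann)
        n_snv = sum(1 for a in ann if a.variant.vclass == "snv")
        assert ti + tv == n_snv


class TestMergeDnps:
    def _annotated(self, positions, hairpin=None):
        hp = hairpin or _simple_hairpin()
        vs = [
            _snv(p, ref="N", alt="G", vid=f"v{p}") for p in positions
        ]
        # use real hairpin bases as REF so nothing is flagged
        vs = [
            Variant(
                id=v.id,
                interval=v.interval,
                ref=hp.sequence[v.interval.start - hp.interval.start].replace("U", "T"),
                alt="G" if hp.sequence[v.interval.start - hp.interval.start] != "G" else "C",
            )
            for v in vs
        ]
        return annotate(vs, [hp])

    def test_adjacent_pair_grouped(self):
        ann = merge_dnps(self._annotated([1013, 1014]))
        groups = {a.variant.id: a.dnp_group for a in ann}
        assert groups["v1013"] is not None
        assert groups["v1013"] == groups["v1014"]
        assert groups["v1013"].startswith("DNP:")

    def test_gap_not_grouped(self):
        ann = merge_dnps(self._annotated([1013, 1015]))
        assert all(a.dnp_group is None for a in ann if not a.variant.id.startswith("merged:"))

    def test_run_of_three_is_single_mnp_run(self):
        ann = merge_dnps(self._annotated([1013, 1014, 1015]))
        labels = {
            a.dnp_group for a in ann if not a.variant.id.startswith("merged:")
        }
        assert len(labels) == 1
        (label,) = labels
        assert label.startswith("MNP3:")

    def test_merged_record_emitted_and_originals_retained(self):
        ann = merge_dnps(self._annotated([1013, 1014]))
        merged = [a for a in ann if a.variant.id.startswith("merged:")]
        assert len(merged) == 1
        assert merged[0].variant.vclass == "mnp"
        assert len(merged[0].variant.ref) == 2
        originals = [a for a in ann if not a.variant.id.startswith("merged:")]
        assert len(originals) == 2

    def test_direct_mnp_record_labeled_dnp(self):
        hp = _simple_hairpin()
        ref2 = hp.sequence[2:4].replace("U", "T")
        v = Variant(
            id="mnp1",
            interval=GenomicInterval("chr1", 1003, 1004, "."),
            ref=ref2,
            alt="".join("A" if b != "A" else "C" for b in ref2),
        )
        ann = merge_dnps(annotate([v], [hp]))
        assert all(a.dnp_group and a.dnp_group.startswith("DNP:") for a in ann)

    def test_idempotent_and_order_invariant(self):
        base = self._annotated([1013, 1014, 1020, 1021, 1022])

        def canon(anns):
            return sorted(
                (a.variant.id, a.variant.interval.start, a.dnp_group, a.mature)
                for a in anns
            )

        once = merge_dnps(base)
        twice = merge_dnps(once)
        assert canon(once) == canon(twice)
        shuffled = list(base)
        random.Random(1).shuffle(shuffled)
        assert canon(merge_dnps(shuffled)) == canon(once)

    def test_planted_runs_recovered(self, small_model):
        fx, hairpins, variants = small_model
        ann = merge_dnps(annotate(variants, hairpins))
        labels = {
            a.variant.id: a.dnp_group
            for a in ann
            if not a.variant.id.startswith("merged:")
        }
        for run in fx.truth["dnp_runs"]:
            got = {labels[i] for i in run["ids"]}
            assert len(got) == 1 and None not in got
            prefix = "DNP:" if run["length"] == 2 else f"MNP{run['length']}:"
            assert got.pop().startswith(prefix)
        # oracle cross-check: runs derived independently from truth positions
        for hp_name in {r["hairpin"] for r in fx.truth["dnp_runs"]}:
            positions = [
                t["pos"]
                for t in fx.truth["variants"]
                if t.get("hairpin") == hp_name and t["vclass"] == "snv"
            ]
            oracle_runs = maximal_adjacent_runs(positions)
            truth_runs = [
                r["positions"]
                for r in fx.truth["dnp_runs"]
                if r["hairpin"] == hp_name
            ]
            assert sorted(oracle_runs) == sorted(truth_runs)
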