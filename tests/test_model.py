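"""Coordinate arithmetic between genome, hairpin, and mature frames."""

from __future__ import annotations

import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseed.model import (
    GenomicInterval,
    MatureMir,
    MirnaHairpin,
    ModelError,
    extract_seed,
    genome_to_mature_position,
    mature_sequence,
    mature_to_genome_position,
    seed_region,
)

from _oracles import oriented_positions


def _hairpin(strand="+", seq="AACGUACGUUGG", start=1001, mat_off=3, mat_len=6):
    hp = MirnaHairpin(
        name="mir-t",
        interval=GenomicInterval("chr1", start, start + len(seq) - 1, strand),
        sequence=seq,
    )
    if strand == "+":
        ms = start + mat_off - 1
        me = ms + mat_len - 1
    else:
        me = start + len(seq) - 1 - (mat_off - 1)
        ms = me - mat_len + 1
    hp.matures.append(
        MatureMir(
            name="miR-t",
            interval=GenomicInterval("chr1", ms, me, strand),
            hairpin_offset=mat_off,
            length=mat_len,
        )
    )
    hp.validate()
    return hp


class TestMatureSequence:
    def test_substring(self):
        hp = _hairpin()
        assert mature_sequence(hp, hp.matures[0]) == "CGUACG"

    def test_whole_hairpin(self):
        hp = _hairpin(mat_off=1, mat_len=12)
        assert mature_sequence(hp, hp.matures[0]) == hp.sequence

    def test_minus_strand_is_reverse_complement_of_plus_slice(self):
        # on the minus strand, the stored transcript-oriented hairpin
        # sequence must equal the reverse complement of the + strand slice
        hp = _hairpin(strand="-")
        mat = hp.matures[0]
        plus_slice_rna = reverse_complement(
            mature_sequence(hp, mat).replace("U", "T")
        ).replace("T", "U")
        walk = oriented_positions(mat.interval.start, mat.interval.end, "-")
        assert len(plus_slice_rna) == len(walk)
        assert mature_sequence(hp, mat) == "CGUACG"


class TestGenomeMaturePosition:
    def test_plus_strand_five_prime_end(self):
        hp = _hairpin(strand="+", start=1010, mat_off=1, mat_len=6)
        mat = hp.matures[0]
        assert genome_to_mature_position(mat, hp, mat.interval.start) == 1

    def test_minus_strand_five_prime_end(self):
        hp = _hairpin(strand="-", start=1010, mat_off=1, mat_len=6)
        mat = hp.matures[0]
        assert genome_to_mature_position(mat, hp, mat.interval.end) == 1

    def test_outside_mature_is_none(self):
        hp = _hairpin()
        mat = hp.matures[0]
        assert genome_to_mature_position(mat, hp, mat.interval.end + 1) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_per_base_walk(self, strand):
        hp = _hairpin(strand=strand, seq="ACGUACGUACGUACGUACGU", mat_off=4, mat_len=9)
        mat = hp.matures[0]
        walk = oriented_positions(mat.interval.start, mat.interval.end, strand)
        for i, g in enumerate(walk):
            assert genome_to_mature_position(mat, hp, g) == i + 1
            assert mature_to_genome_position(mat, hp, i + 1) == g

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_identity(self, strand):
        hp = _hairpin(strand=strand, seq="ACGUACGUACGUACGUACGU", mat_off=4, mat_len=9)
        mat = hp.matures[0]
        for q in range(1, mat.length + 1):
            g = mature_to_genome_position(mat, hp, q)
            assert genome_to_mature_position(mat, hp, g) == q


class TestExtractSeed:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("UAAGGCACGCGGU", 6, "AAGGCA"),
            ("UAAGGCACGCGGU", 7, "AAGGCAC"),
            ("ACGUACGUACGUACGUACGUA", 6, "CGUACG"),
            ("ACGUACGUACGUACGUACGUA", 7, "CGUACGU"),
            ("ACGUACG", 6, "CGUACG"),  # minimal length k+1
        ],
    )
    def test_positions_2_to_k_plus_1(self, seq, k, expected):
        assert extract_seed(seq, k) == expected

    def test_too_short_raises(self):
        with pytest.raises(ModelError):
            extract_seed("ACGUACG", 7)  # needs >= 8 nt

    def test_bad_k_raises(self):
        with pytest.raises(ModelError):
            extract_seed("ACGUACGUA", 5)


class TestSeedRegion:
    def test_seed6_is_prefix_of_seed7(self):
        hp = _hairpin(seq="ACGUACGUACGUACGUACGU", mat_off=2, mat_len=12)
        mat = hp.matures[0]
        s6 = seed_region(mat, hp, 6)
        s7 = seed_region(mat, hp, 7)
        assert s7.seed_sequence.startswith(s6.seed_sequence)
        assert list(s6.mature_positions) == [2, 3, 4, 5, 6, 7]
        assert list(s7.mature_positions) == [2, 3, 4, 5, 6, 7, 8]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_genomic_interval_matches_enumeration(self, strand):
        hp = _hairpin(strand=strand, seq="ACGUACGUACGUACGUACGU", mat_off=3, mat_len=10)
        mat = hp.matures[0]
        for k in (6, 7):
            sr = seed_region(mat, hp, k)
            walk = oriented_positions(mat.interval.start, mat.interval.end, strand)
            expected = sorted(walk[1 : k + 1])
            assert (sr.genomic_interval.start, sr.genomic_interval.end) == (
                expected[0],
                expected[-1],
            )
            assert sr.seed_sequence == mature_sequence(hp, mat)[1 : k + 1]

    def test_mature_too_short(self):
        hp = _hairpin(mat_len=6)
        with pytest.raises(ModelError):
            seed_region(hp.matures[0], hp, 6)


class TestInvariants:
    def test_interval_rejects_inverted_bounds(self):
        with pytest.raises(ModelError):
            GenomicInterval("chr1", 10, 5)

    def test_mature_outside_hairpin_rejected(self):
        hp = MirnaHairpin(
            name="mir-x", interval=GenomicInterval("chr1", 100, 150, "+")
        )
        hp.matures.append(
            MatureMir(
                name="miR-x",
                interval=GenomicInterval("chr1", 140, 160, "+"),
                hairpin_offset=41,
                length=21,
            )
        )
        with pytest.raises(ModelError, match="miR-x"):
            hp.validate()

    @settings(max_examples=50, deadline=None)
    @given(
        start=st.integers(min_value=1, max_value=10**6),
        length=st.integers(min_value=8, max_value=30),
        offset=st.integers(min_value=1, max_value=10),
        strand=st.sampled_from(["+", "-"]),
        data=st.data(),
    )
    def test_round_trip_property(self, start, length, offset, strand, data):
        hp_len = offset + length - 1 + data.draw(st.integers(0, 20))
        seq = "".join(
            data.draw(
                st.lists(
                    st.sampled_from("ACGU"), min_size=hp_len, max_size=hp_len
                )
            )
        )
        hp = MirnaHairpin(
            name="mir-h",
            interval=GenomicInterval("chr1", start, start + hp_len - 1, strand),
            sequence=seq,
        )
        if strand == "+":
            ms = start + offset - 1
            me = ms + length - 1
        else:
            me = start + hp_len - 1 - (offset - 1)
            ms = me - length + 1
        mat = MatureMir(
            name="miR-h",
            interval=GenomicInterval("chr1", ms, me, strand),
            hairpin_offset=offset,
            length=length,
        )
        hp.matures.append(mat)
        hp.validate()
        for q in range(1, length + 1):
            g = mature_to_genome_position(mat, hp, q)
            assert mat.interval.contains(g)
            assert genome_to_mature_position(mat, hp, g) == q
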