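from __future__ import annotations

import pytest

from mirseed import io_formats as iof
from mirseed.simulate import FixtureSpec, generate_fixture, mir96_like_fixture


def load_fixture_model(fx):
    """Read a generated fixture back through the public I/O layer."""
    hairpins = iof.attach_sequences(
        iof.read_mirna_gff(fx.paths["mirna_gff"]),
        iof.read_hairpin_fasta(fx.paths["hairpin_fasta"]),
    )
    variants = iof.read_vcf(fx.paths["vcf"])
    return hairpins, variants


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """Default-sized fixture: 30 miRNAs, ~40 variants, features, phenotypes."""
    return generate_fixture(
        FixtureSpec(seed=11), tmp_path_factory.mktemp("small_fx")
    )


@pytest.fixture(scope="session")
def small_model(small_fixture):
    hairpins, variants = load_fixture_model(small_fixture)
    return small_fixture, hairpins, variants


@pytest.fixture(scope="session")
def large_fixture(tmp_path_factory):
    """200 miRNAs (half minus strand), ~2000 variants of all classes."""
    spec = FixtureSpec(
        seed=42,
        n_chromosomes=2,
        chrom_length=120_000,
        n_mirnas=200,
        fraction_minus_strand=0.5,
        n_seed_snvs=600,
        n_mature_snvs=300,
        n_precursor_snvs=350,
        n_outside_snvs=470,
        n_deletions=50,
        n_insertions=30,
        n_planted_dnps=60,
        n_planted_triples=20,
        n_planted_seed_switches=20,
        n_qtl=30,
        n_fragile_sites=15,
        n_host_genes=30,
    )
    return generate_fixture(spec, tmp_path_factory.mktemp("large_fx"))


@pytest.fixture(scope="session")
def large_model(large_fixture):
    hairpins, variants = load_fixture_model(large_fixture)
    return large_fixture, hairpins, variants


@pytest.fixture(scope="session")
def switch_fixture(tmp_path_factory):
    """500 miRNAs with 50 planted seed-switch pairs and 200 features."""
    spec = FixtureSpec(
        seed=7,
        n_chromosomes=3,
        chrom_length=160_000,
        n_mirnas=500,
        fraction_minus_strand=0.5,
        n_seed_snvs=30,
        n_mature_snvs=10,
        n_precursor_snvs=10,
        n_outside_snvs=10,
        n_deletions=0,
        n_insertions=0,
        n_planted_dnps=5,
        n_planted_triples=0,
        n_planted_seed_switches=50,
        n_qtl=150,
        n_fragile_sites=50,
        n_host_genes=60,
    )
    return generate_fixture(spec, tmp_path_factory.mktemp("switch_fx"))


@pytest.fixture(scope="session")
def switch_model(switch_fixture):
    hairpins, variants = load_fixture_model(switch_fixture)
    return switch_fixture, hairpins, variants


@pytest.fixture(scope="session")
def mir96_fixture(tmp_path_factory):
    return mir96_like_fixture(tmp_path_factory.mktemp("mir96_fx"))
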