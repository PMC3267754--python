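"""Nested fixed-effects genotype-phenotype model and multi-trait scan."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirseed.association import (
    fit_nested_model,
    genotype_group_summary,
    scan_traits,
)
from mirseed.model import ModelError


def simulate_trait(
    rng,
    trait="t1",
    strains_per_genotype=2,
    n_per_cell=20,
    delta=2.0,
    sigma=0.1,
    sexes=("f", "m"),
    sex_effect=0.0,
    strain_sd=0.0,
    group="g",
):
    """Balanced two-genotype panel: value = 10 + G/2 +/- strain + sex + noise."""
    rows = []
    strains = [f"S{i}" for i in range(2 * strains_per_genotype)]
    for i, s in enumerate(strains):
        g = "CC" if i < strains_per_genotype else "TT"
        gterm = delta / 2 if g == "TT" else -delta / 2
        s_eff = rng.normal(0, strain_sd) if strain_sd else 0.0
        for sex in sexes:
            x_eff = sex_effect / 2 if sex == "m" else -sex_effect / 2
            for v in 10.0 + gterm + s_eff + x_eff + rng.normal(0, sigma, n_per_cell):
                rows.append(
                    {
                        "strain": s,
                        "sex": sex,
                        "genotype": g,
                        "trait": trait,
                        "group": group,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


class TestFitNestedModel:
    def test_balanced_effect_equals_raw_mean_difference(self):
        rng = np.random.default_rng(1)
        df = simulate_trait(rng, delta=2.0, sigma=0.1)
        res = fit_nested_model(df, trait="t1")
        raw = df[df.genotype == "TT"].value.mean() - df[df.genotype == "CC"].value.mean()
        assert res.genotype_effect == pytest.approx(raw, abs=1e-8)

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(2)
        df = simulate_trait(rng, delta=2.0, sigma=0.1, n_per_cell=20)
        res = fit_nested_model(df, trait="t1")
        assert res.genotype_effect == pytest.approx(2.0, abs=3 * res.se)
        assert res.p_value < 1e-6

    def test_zero_variance_trait(self):
        df = simulate_trait(np.random.default_rng(3), delta=0.0, sigma=0.0)
        res = fit_nested_model(df, trait="t1")
        assert (res.genotype_effect, res.p_value) == (0.0, 1.0)

    def test_single_genotype_not_estimable(self):
        rng = np.random.default_rng(4)
        df = simulate_trait(rng)
        df = df[df.genotype == "CC"]
        res = fit_nested_model(df, trait="t1")
        assert not res.estimable
        assert res.reason == "single genotype level"

    def test_single_sex_drops_sex_term(self):
        rng = np.random.default_rng(5)
        df = simulate_trait(rng, sexes=("f",))
        res = fit_nested_model(df, trait="t1")
        assert "sex" in res.dropped_terms
        assert res.estimable

    def test_location_equivariance(self):
        rng = np.random.default_rng(6)
        df = simulate_trait(rng, delta=1.5, sigma=0.5)
        res = fit_nested_model(df, trait="t1")
        shifted = df.assign(value=df.value + 100.0)
        res2 = fit_nested_model(shifted, trait="t1")
        assert res2.genotype_effect == pytest.approx(res.genotype_effect, abs=1e-9)
        assert res2.se == pytest.approx(res.se, rel=1e-9)
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-6)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(7)
        df = simulate_trait(rng, delta=1.0, sigma=0.3)
        res = fit_nested_model(df, trait="t1")
        shuffled = df.sample(frac=1.0, random_state=8).reset_index(drop=True)
        res2 = fit_nested_model(shuffled, trait="t1")
        assert res2.genotype_effect == pytest.approx(res.genotype_effect, abs=1e-10)
        assert res2.se == pytest.approx(res.se, rel=1e-10)
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-8)

    def test_strain_error_denominator_is_more_conservative(self):
        """With real strain-to-strain heterogeneity, testing against the
        strain-within-genotype mean square gives a larger p than the
        residual denominator."""
        rng = np.random.default_rng(9)
        df = simulate_trait(
            rng, strains_per_genotype=5, delta=1.0, sigma=0.5, strain_sd=1.0
        )
        p_resid = fit_nested_model(df, trait="t1").p_value
        p_strain = fit_nested_model(df, trait="t1", strain_error=True).p_value
        assert p_strain > p_resid

    def test_genotype_varying_within_strain_rejected(self):
        df = simulate_trait(np.random.default_rng(10))
        df.loc[df.index[:5], "genotype"] = "TT"
        with pytest.raises(ModelError, match="inbred"):
            fit_nested_model(df, trait="t1")


class TestScanTraits:
    def test_planted_effects_all_significant(self):
        rng = np.random.default_rng(11)
        frames = [
            simulate_trait(
                rng, trait=f"eff{i}", delta=5 * 0.5, sigma=0.5, n_per_cell=10
            )
            for i in range(10)
        ]
        scan = scan_traits(pd.concat(frames), alpha=0.01)
        assert scan.results["significant"].all()
        assert len(scan.significant) == 10

    def test_empty_input(self):
        scan = scan_traits(pd.DataFrame(columns=["strain", "sex", "genotype", "trait", "group", "value"]))
        assert scan.results.empty and scan.significant.empty

    def test_skipped_traits_reported(self):
        rng = np.random.default_rng(12)
        good = simulate_trait(rng, trait="ok")
        bad = simulate_trait(rng, trait="mono")
        bad = bad[bad.genotype == "CC"]
        scan = scan_traits(pd.concat([good, bad]))
        assert list(scan.skipped["trait"]) == ["mono"]
        assert list(scan.results["trait"]) == ["ok"]

    def test_group_counts(self):
        rng = np.random.default_rng(13)
        frames = [
            simulate_trait(rng, trait=f"t{i}", delta=3.0, sigma=0.1, group=g)
            for i, g in enumerate(["bone", "bone", "behavior"])
        ]
        scan = scan_traits(pd.concat(frames), alpha=0.01)
        assert scan.group_counts.to_dict() == {"bone": 2, "behavior": 1}

    def test_bh_adjustment_is_not_more_liberal(self):
        rng = np.random.default_rng(14)
        frames = [
            simulate_trait(rng, trait=f"n{i}", delta=0.0, sigma=1.0)
            for i in range(20)
        ]
        df = pd.concat(frames)
        raw = scan_traits(df, alpha=0.05)
        bh = scan_traits(df, alpha=0.05, bh=True)
        assert len(bh.significant) <= len(raw.significant)


class TestGroupSummary:
    def test_known_cell_means(self):
        df = pd.DataFrame(
            {
                "strain": ["S1"] * 4 + ["S2"] * 4,
                "sex": ["f", "f", "m", "m"] * 2,
                "genotype": ["CC"] * 4 + ["TT"] * 4,
                "trait": ["t"] * 8,
                "group": ["g"] * 8,
                "value": [1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0],
            }
        )
        out = genotype_group_summary(df, "t")
        cells = {(r.genotype, r.sex): r.mean for r in out.itertuples()}
        assert cells == {("CC", "f"): 2.0, ("CC", "m"): 3.0, ("TT", "f"): 6.0, ("TT", "m"): 7.0}

    def test_single_sex_collapses(self):
        rng = np.random.default_rng(15)
        df = simulate_trait(rng, sexes=("f",))
        out = genotype_group_summary(df, "t1")
        assert "sex" not in out.columns
        assert set(out["genotype"]) == {"CC", "TT"}

    def test_lean_vs_fat_ordering(self, small_fixture):
        """Planted positive genotype effect: TT cells exceed CC in both
        sexes, the pattern behind the fat-weight comparison."""
        import mirseed.io_formats as iof

        df = iof.read_phenotypes(small_fixture.paths["phenotypes"])
        trait = next(
            t["trait"]
            for t in small_fixture.truth["phenotypes"]
            if t["effect_size"] > 0
        )
        out = genotype_group_summary(df, trait)
        for sex in ("f", "m"):
            sub = out[out.sex == sex].set_index("genotype")["mean"]
            assert sub["TT"] > sub["CC"]

    def test_missing_trait(self):
        df = simulate_trait(np.random.default_rng(16))
        with pytest.raises(ModelError):
            genotype_group_summary(df, "nope")
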