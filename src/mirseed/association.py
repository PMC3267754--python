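"""Genotype-to-phenotype association for inbred strain panels.

Model
-----
For one trait, an observation from strain *j* of genotype *i* and sex *k*
is modeled with fixed effects

    y_ijkl = mu + G_i + L_j(i) + S_k + e_ijkl

where ``G`` is the seed-SNP genotype (two levels, e.g. CC vs TT), ``L`` the
strain nested within genotype (inbred strains carry one genotype each, so
strain determines genotype), ``S`` the sex, and ``e`` i.i.d. residual
error.  Because strain is nested in genotype, the fit uses a full-rank
strain + sex design and the genotype effect is reported as the difference
of genotype least-squares means — the unweighted average of strain means
within each genotype — which is invariant to the coding.

The default F/t test uses the residual mean square as denominator; with
``strain_error=True`` the strain-within-genotype mean square is used
instead, the classical choice when strains rather than animals are the
experimental units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ModelError

#: tolerance below which a trait is treated as constant (zero variance)
_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class PhenotypeRecord:
    """One trait observation keyed by strain, sex, and genotype."""

    strain: str
    sex: str
    genotype: str
    trait: str
    group: str
    value: float


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class AssociationResult:
    """Fitted genotype contrast for one trait.

    ``genotype_effect`` is the second-minus-first (sorted genotype labels,
    e.g. TT - CC) difference of least-squares means, in trait units.
    """

    trait: str
    genotype_effect: Optional[float]
    se: Optional[float]
    p_value: Optional[float]
    n_used: int
    genotype_levels: tuple[str, ...] = ()
    dropped_terms: list[str] = field(default_factory=list)
    estimable: bool = True
    reason: Optional[str] = None


def _design(df: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Full-rank design: intercept + strain dummies (reference = first
    strain) + sex dummy when both sexes occur."""
    strains = sorted(df["strain"].unique())
    sexes = sorted(df["sex"].unique())
    dropped = []
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for s in strains[1:]:
        cols.append((df["strain"] == s).to_numpy(float))
        names.append(f"strain[{s}]")
    if len(sexes) > 1:
        cols.append((df["sex"] == sexes[1]).to_numpy(float))
        names.append(f"sex[{sexes[1]}]")
    else:
        dropped.append("sex")
    X = np.column_stack(cols)
    meta = {"strains": strains, "sexes": sexes}
    return X, names, dropped, meta


def _genotype_contrast(
    names: list[str], strains: list[str], strain_genotype: dict[str, str]
) -> tuple[np.ndarray, tuple[str, str]]:
    """Contrast vector whose inner product with the coefficients is
    LS-mean(genotype2) - LS-mean(genotype1)."""
    levels = sorted(set(strain_genotype.values()))
    if len(levels) != 2:
        raise ModelError(f"need exactly 2 genotype levels, got {levels}")
    g1, g2 = levels
    n1 = sum(1 for s in strains if strain_genotype[s] == g1)
    n2 = sum(1 for s in strains if strain_genotype[s] == g2)
    c = np.zeros(len(names))
    for i, name in enumerate(names):
        if not name.startswith("strain["):
            continue
        s = name[len("strain[") : -1]
        if strain_genotype[s] == g2:
            c[i] = 1.0 / n2
        else:
            c[i] = -1.0 / n1
    return c, (g1, g2)


def fit_nested_model(
    records: pd.DataFrame | Sequence[PhenotypeRecord],
    trait: Optional[str] = None,
    strain_error: bool = False,
) -> AssociationResult:
    """Fit the nested fixed-effects model for one trait.

    Returns a non-estimable result (rather than raising) when only one
    genotype level is observed.  Zero-variance traits get effect 0 and
    p = 1 by convention.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if trait is not None:
        df = df[df["trait"] == trait]
    elif "trait" in df.columns and df["trait"].nunique() > 1:
        raise ModelError("records span multiple traits; pass trait=")
    tname = trait or (df["trait"].iloc[0] if len(df) else "")
    df = df.dropna(subset=["value"])
    n = len(df)

    strain_genotype = (
        df.drop_duplicates("strain").set_index("strain")["genotype"].to_dict()
    )
    if df.groupby("strain")["genotype"].nunique().gt(1).any():
        raise ModelError("genotype must be constant within an inbred strain")
    levels = tuple(sorted(df["genotype"].unique()))
    if len(levels) < 2:
        return AssociationResult(
            trait=tname,
            genotype_effect=None,
            se=None,
            p_value=None,
            n_used=n,
            genotype_levels=levels,
            estimable=False,
            reason="single genotype level",
        )
    if len(df["strain"].unique()) < 2:
        return AssociationResult(
            trait=tname,
            genotype_effect=None,
            se=None,
            p_value=None,
            n_used=n,
            genotype_levels=levels,
            estimable=False,
            reason="fewer than 2 strains",
        )

    y = df["value"].to_numpy(float)
    if np.var(y) < _ZERO_VAR_TOL:
        return AssociationResult(
            trait=tname,
            genotype_effect=0.0,
            se=0.0,
            p_value=1.0,
            n_used=n,
            genotype_levels=levels,
            reason="zero variance",
        )

    X, names, dropped, meta = _design(df)
    c, _ = _genotype_contrast(names, meta["strains"], strain_genotype)
    res = sm.OLS(y, X).fit()
    effect = float(c @ res.params)
    # unscaled contrast variance c'(X'X)^-1 c, shared by both denominators
    unscaled = float(c @ (res.cov_params() / res.scale) @ c)

    if not strain_error:
        se = float(np.sqrt(unscaled * res.scale))
        tstat = effect / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(tstat), res.df_resid)) if se > 0 else 1.0
    else:
        ms_lg, df_lg = _strain_within_genotype_ms(df, y, X, names, res)
        if df_lg < 1:
            return AssociationResult(
                trait=tname,
                genotype_effect=effect,
                se=None,
                p_value=None,
                n_used=n,
                genotype_levels=levels,
                dropped_terms=dropped,
                estimable=False,
                reason="fewer than 2 strains per genotype for strain-level error",
            )
        se = float(np.sqrt(unscaled * ms_lg))
        tstat = effect / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(tstat), df_lg)) if se > 0 else 1.0

    return AssociationResult(
        trait=tname,
        genotype_effect=effect,
        se=se,
        p_value=min(max(p, 0.0), 1.0),
        n_used=n,
        genotype_levels=levels,
        dropped_terms=dropped,
    )


def _strain_within_genotype_ms(df, y, X_full, names, res_full):
    """Mean square for strain-within-genotype: the sequential SS between a
    genotype(+sex) model and the strain(+sex) model."""
    cols = [np.ones(len(df))]
    g_levels = sorted(df["genotype"].unique())
    for g in g_levels[1:]:
        cols.append((df["genotype"] == g).to_numpy(float))
    sex_cols = [i for i, n in enumerate(names) if n.startswith("sex[")]
    for i in sex_cols:
        cols.append(X_full[:, i])
    X_red = np.column_stack(cols)
    res_red = sm.OLS(y, X_red).fit()
    ss = float(res_red.ssr - res_full.ssr)
    n_strains = df["strain"].nunique()
    dof = n_strains - len(g_levels)
    return (ss / dof if dof > 0 else np.nan), dof


@dataclass
class ScanResult:
    """Multi-trait scan output."""

    results: pd.DataFrame
    significant: pd.DataFrame
    skipped: pd.DataFrame  # trait, reason
    group_counts: pd.Series  # significant traits per group
    alpha: float


def scan_traits(
    records: pd.DataFrame | Sequence[PhenotypeRecord],
    alpha: float = 0.01,
    strain_error: bool = False,
    bh: bool = False,
) -> ScanResult:
    """Fit the nested model for every trait and flag significance.

    By default significance is the raw two-sided p < ``alpha`` with no
    multiple-testing correction; ``bh=True`` applies Benjamini-Hochberg
    and thresholds the adjusted p instead.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    rows, skipped = [], []
    for tname, sub in df.groupby("trait", sort=True):
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        result = fit_nested_model(sub, trait=tname, strain_error=strain_error)
        if not result.estimable:
            skipped.append({"trait": tname, "reason": result.reason})
            continue
        rows.append(
            {
                "trait": tname,
                "group": group,
                "genotype_effect": result.genotype_effect,
                "se": result.se,
                "p_value": result.p_value,
                "n_used": result.n_used,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=["trait", "group", "genotype_effect", "se", "p_value", "n_used"],
    )
    if bh and len(results):
        results["p_adjusted"] = multipletests(
            results["p_value"], method="fdr_bh"
        )[1]
        results["significant"] = results["p_adjusted"] < alpha
    elif len(results):
        results["significant"] = results["p_value"] < alpha
    else:
        results["significant"] = pd.Series(dtype=bool)
    significant = results[results["significant"]].reset_index(drop=True)
    group_counts = (
        significant.groupby("group").size().sort_index()
        if len(significant)
        else pd.Series(dtype=int)
    )
    return ScanResult(
        results=results,
        significant=significant,
        skipped=pd.DataFrame(skipped, columns=["trait", "reason"]),
        group_counts=group_counts,
        alpha=alpha,
    )


def genotype_group_summary(
    records: pd.DataFrame | Sequence[PhenotypeRecord], trait: str
) -> pd.DataFrame:
    """n, mean, and SD per (genotype, sex) cell for one trait — the table
    behind a lean-vs-fat style genotype comparison plot.  Single-sex
    traits collapse the sex dimension."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ModelError(f"trait {trait!r} not present")
    keys = ["genotype"] if sub["sex"].nunique() == 1 else ["genotype", "sex"]
    out = (
        sub.groupby(keys)["value"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return out
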