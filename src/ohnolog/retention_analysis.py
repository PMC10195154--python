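"""Retention vs expression level and functional category.

Expression level is log10(FPKM + 0.1) (the offset keeps zero-FPKM genes).
The cross-species retention rate of an ancestral gene is the number of
ingroup species retaining both WGD copies divided by the number of species
with at least one ortholog; genes with no ingroup ortholog are excluded
rather than scored zero. Category effects are screened with an
expression-controlled permutation test (retention labels shuffled within
expression strata) and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import BOTH, NA


def expression_level(fpkm) -> np.ndarray | float:
    """log10(FPKM + 0.1); accepts scalars or arrays."""
    arr = np.asarray(fpkm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("FPKM must be >= 0")
    out = np.log10(arr + 0.1)
    return float(out) if out.ndim == 0 else out


def cross_species_retention(matrix: pd.DataFrame) -> pd.Series:
    """Per-pair retention rate across species: BOTH / (BOTH + ONE).

    ``matrix``: pairs x ingroup species with {BOTH, ONE, NA}; rows that
    are all NA (no ortholog anywhere) are dropped.
    """
    has = (matrix != NA).sum(axis=1)
    both = (matrix == BOTH).sum(axis=1)
    rates = (both / has)[has > 0]
    rates.name = "retention"
    return rates


@dataclass
class RetentionBin:
    bin_index: int
    expr_lo: float
    expr_hi: float
    mean_retention: float
    ci95: float
    n: int


def binned_retention(
    expression: pd.Series, rates: pd.Series, n_bins: int = 14
) -> pd.DataFrame:
    """Equal-count expression bins with mean retention and a normal
    approximation 95% CI (mean +/- 1.96 SE)."""
    joined = pd.DataFrame({"expr": expression, "rate": rates}).dropna()
    if len(joined) < n_bins:
        raise ValueError("fewer genes than bins")
    order = joined["expr"].rank(method="first")
    joined["bin"] = pd.qcut(order, n_bins, labels=False)
    rows = []
    for b, grp in joined.groupby("bin", sort=True):
        se = grp["rate"].std(ddof=1) / math.sqrt(len(grp)) if len(grp) > 1 else 0.0
        rows.append(
            RetentionBin(
                bin_index=int(b),
                expr_lo=float(grp["expr"].min()),
                expr_hi=float(grp["expr"].max()),
                mean_retention=float(grp["rate"].mean()),
                ci95=float(1.96 * se),
                n=len(grp),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def retention_trend(binned: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of mean retention across expression bins."""
    rho, p = stats.spearmanr(binned["bin_index"], binned["mean_retention"])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# functional-category bias


def category_bias(
    categories: pd.Series,
    rates_clade_a: pd.Series,
    rates_clade_b: pd.Series,
    expression: pd.Series | None = None,
    n_strata: int = 5,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Per-category retention in two clades, their cross-clade Pearson r,
    and expression-controlled permutation enrichment with BH FDR.

    Returns ``(table, r, p)``. The permutation shuffles overall retention
    rates within expression strata, so categories enriched merely because
    their genes are highly expressed are not flagged.
    """
    df = pd.DataFrame(
        {
            "category": categories,
            "rate_a": rates_clade_a,
            "rate_b": rates_clade_b,
        }
    ).dropna(subset=["category"])
    df["rate"] = df[["rate_a", "rate_b"]].mean(axis=1)
    if df["category"].nunique() < 2:
        raise ValueError("need >= 2 categories")

    per_cat = df.groupby("category").agg(
        mean_a=("rate_a", "mean"), mean_b=("rate_b", "mean"),
        mean=("rate", "mean"), n=("rate", "size"),
    )
    r, p = stats.pearsonr(per_cat["mean_a"], per_cat["mean_b"])

    if expression is not None:
        df["stratum"] = pd.qcut(
            expression.reindex(df.index).rank(method="first"), n_strata, labels=False
        )
    else:
        df["stratum"] = 0
    rng = np.random.default_rng(seed)
    cats = per_cat.index.to_numpy()
    obs = per_cat["mean"].to_numpy()
    perm_ge = np.zeros(len(cats))
    perm_le = np.zeros(len(cats))
    rate_vals = df["rate"].to_numpy().copy()
    strata = [np.flatnonzero(df["stratum"].to_numpy() == s) for s in range(df["stratum"].nunique())]
    cat_codes = pd.Categorical(df["category"], categories=cats).codes
    counts = np.bincount(cat_codes, minlength=len(cats))
    for _ in range(n_permutations):
        shuffled = rate_vals.copy()
        for idx in strata:
            shuffled[idx] = rng.permutation(shuffled[idx])
        means = np.bincount(cat_codes, weights=shuffled, minlength=len(cats)) / counts
        perm_ge += means >= obs - 1e-12
        perm_le += means <= obs + 1e-12
    p_enr = (perm_ge + 1) / (n_permutations + 1)
    p_dep = (perm_le + 1) / (n_permutations + 1)
    p_two = np.minimum(1.0, 2 * np.minimum(p_enr, p_dep))
    per_cat["perm_p"] = p_two
    per_cat["fdr_q"] = multipletests(p_two, method="fdr_bh")[1]
    per_cat["direction"] = np.where(obs >= df["rate"].mean(), "excess", "scarcity")
    return per_cat.reset_index(), float(r), float(p)
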