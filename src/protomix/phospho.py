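"""Kinase-substrate analysis on phosphosite matrices: tumor/NAT fold-change
ranking of annotated substrate events, grade comparisons, and the
module-correlation test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "match_annotation",
    "substrate_rank",
    "grade_compare",
    "module_corr_test",
]


def match_annotation(site_matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep annotation rows whose (kinase, site) reference a measured site;
    the dropped count is recorded in ``.attrs['n_dropped']``."""
    keep = annotation["site"].isin(site_matrix.index)
    out = annotation[keep].reset_index(drop=True)
    out.attrs["n_dropped"] = int((~keep).sum())
    return out


def substrate_rank(
    site_matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    fold: float = 1.5,
) -> dict:
    """Rank annotated substrate events per tumor by log2 fold change over
    the paired NAT.

    ``pairs`` has columns ``tumor`` and ``nat``; unpaired tumors (missing
    NAT column) are skipped. Events with fold change > log2(``fold``) are
    ranked descending (rank 1 = largest increase). Returns the long rank
    table and a per-event summary counting tumors where the event ranked
    first, flagging events that top a majority of ranked tumors.
    """
    ann = match_annotation(site_matrix, annotation)
    if ann.empty:
        raise ValueError("annotation is empty after matching to the site matrix")
    rows = []
    skipped = []
    n_ranked_tumors = 0
    for rec in pairs.itertuples():
        if rec.tumor not in site_matrix.columns or rec.nat not in site_matrix.columns:
            skipped.append(rec.tumor)
            continue
        fc = site_matrix[rec.tumor] - site_matrix[rec.nat]
        ev = fc.loc[ann["site"].unique()].dropna()
        passing = ev[ev > np.log2(fold)].sort_values(ascending=False)
        if len(passing):
            n_ranked_tumors += 1
        for rank, (site, val) in enumerate(passing.items(), start=1):
            rows.append((rec.tumor, site, float(val), rank))
    table = pd.DataFrame(rows, columns=["tumor", "site", "log2fc", "rank"])
    top_counts = (
        table[table["rank"] == 1].groupby("site").size()
        if len(table) else pd.Series(dtype=int)
    )
    summary = pd.DataFrame({"n_top_ranked": top_counts})
    summary["majority"] = summary["n_top_ranked"] > n_ranked_tumors / 2.0
    kin = ann.set_index("site")["kinase"]
    summary["kinase"] = kin.reindex(summary.index)
    return {"ranks": table, "summary": summary.sort_values("n_top_ranked", ascending=False),
            "skipped_tumors": skipped, "n_ranked_tumors": n_ranked_tumors}


def grade_compare(
    site_matrix: pd.DataFrame,
    grades: pd.Series,
    low=(1, 2),
    high=(3, 4),
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per site between low- and high-grade
    strata (p < 0.05 convention left to the caller)."""
    samples = site_matrix.columns.intersection(grades.index)
    g = grades.loc[samples]
    lo_cols = g.index[g.isin(low)]
    hi_cols = g.index[g.isin(high)]
    if len(lo_cols) < 3 or len(hi_cols) < 3:
        raise ValueError("each grade stratum needs >= 3 samples")
    rows = []
    for site in site_matrix.index:
        a = site_matrix.loc[site, lo_cols].dropna().to_numpy(dtype=float)
        b = site_matrix.loc[site, hi_cols].dropna().to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            continue
        u, p = sps.mannwhitneyu(b, a, alternative="two-sided")
        rows.append((site, float(u), float(p),
                     float(np.median(b) - np.median(a))))
    return pd.DataFrame(rows, columns=["site", "U", "p", "median_diff"]).set_index("site")


def _pairwise_corrs(matrix: pd.DataFrame, genes) -> np.ndarray:
    sub = matrix.loc[matrix.index.intersection(pd.Index(genes))]
    if len(sub) < 2:
        return np.array([])
    C = np.corrcoef(sub.to_numpy(dtype=float))
    iu = np.triu_indices(len(sub), k=1)
    return C[iu]


def module_corr_test(
    target: pd.DataFrame,
    comparator: pd.DataFrame,
    modules: dict,
    min_genes: int = 3,
) -> pd.DataFrame:
    """One-sided t-test that within-module pairwise correlations are higher
    in the target data type than in the comparator.

    Modules with fewer than ``min_genes`` members measured in both data
    types are skipped.
    """
    rows = []
    for name, genes in modules.items():
        shared = [g for g in genes
                  if g in target.index and g in comparator.index]
        if len(shared) < min_genes:
            continue
        a = _pairwise_corrs(target, shared)
        b = _pairwise_corrs(comparator, shared)
        if a.size < 2 or b.size < 2:
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        p_one = p / 2.0 if t > 0 else 1.0 - p / 2.0
        rows.append((name, len(shared), float(a.mean()), float(b.mean()),
                     float(t), float(p_one)))
    return pd.DataFrame(
        rows,
        columns=["module", "n_genes", "mean_corr_target",
                 "mean_corr_comparator", "t", "p_one_sided"],
    ).set_index("module")
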