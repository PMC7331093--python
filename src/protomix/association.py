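"""Cis and trans association of DNA-level features with molecular traits:
covariate-adjusted regression, permutation empirical FDR, directional
biological filters, R-squared decomposition, signed pathway scoring, and
multivariate clinical association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (
    bh_adjust,
    efdr_threshold,
    inverse_normal_transform,
    ranksum_set_test,
    signed_logp_scores,
)

__all__ = [
    "trans_assoc",
    "pathway_score",
    "CisResult",
    "cis_assoc",
    "r2_decomposition",
    "clinical_multivariate",
]

CIS_CONFIGURATIONS = (
    "none", "mrna_only", "protein_only", "phospho_only",
    "mrna_protein", "mrna_phospho", "protein_phospho", "all_three",
)


def _design_matrix(feature: pd.Series, covariates: pd.DataFrame | None,
                   samples: pd.Index) -> np.ndarray:
    cols = [np.ones(len(samples)), feature.loc[samples].to_numpy(dtype=float)]
    if covariates is not None:
        cov = covariates.loc[samples]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int = 1):
    """OLS of every column of Y on X; returns (beta, t, p) for X[:, col]."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    beta = H @ Y                                   # k x G
    resid = Y - X @ beta
    dof = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * XtX_inv[col, col], 1e-300, None))
    t = beta[col] / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta[col], t, p


def trans_assoc(
    feature: pd.Series,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    efdr: float = 0.10,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Trans association of one genomic feature with every trait entry.

    Each trait row is rank-transformed to a standard normal, regressed on
    the feature plus covariates, and the feature's t statistic collected.
    The significance cutoff T* is the smallest T whose averaged empirical
    FDR -- permuted exceedance count over observed exceedance count, from
    ``n_perm`` shuffles of the outcome rows -- is below ``efdr``.
    """
    if float(np.ptp(feature.to_numpy(dtype=float))) == 0.0:
        raise ValueError("feature is constant across samples")
    if n_perm < 10:
        warnings.warn(f"n_perm={n_perm} is small for eFDR estimation", stacklevel=2)
    rng = np.random.default_rng(seed)
    samples = traits.columns
    if normalize:
        Y = np.vstack([inverse_normal_transform(traits.loc[g]) for g in traits.index]).T
    else:
        Y = traits.T.to_numpy(dtype=float)
    X = _design_matrix(feature, covariates, samples)

    beta, t_obs, p = _ols_t(X, Y)
    null = np.empty((n_perm, Y.shape[1]))
    n = Y.shape[0]
    for b in range(n_perm):
        Yp = Y[rng.permutation(n)]
        _, t_p, _ = _ols_t(X, Yp)
        null[b] = np.abs(t_p)
    thr, efdr_at = efdr_threshold(np.abs(t_obs), null, level=efdr)

    res = pd.DataFrame({
        "beta": beta,
        "t": t_obs,
        "p": p,
    }, index=traits.index)
    res["threshold"] = thr
    res["efdr_at_threshold"] = efdr_at
    res["significant"] = np.abs(t_obs) > thr
    res["direction"] = np.where(beta > 0, "positive", "negative")
    return res


def pathway_score(
    assoc: pd.DataFrame,
    gene_sets: dict,
    logp_base: str = "e",
) -> pd.DataFrame:
    """Signed pathway scores from per-gene association summaries.

    Computes T = -sign(beta)*log(p) per gene, rank-sum tests in-set vs
    out-of-set T values (two-sided), BH-adjusts across sets, and reports
    score = +/- log10(adjusted p) signed by direction (up when the in-set
    median T exceeds the out-set median).
    """
    T = pd.Series(
        signed_logp_scores(assoc["beta"].to_numpy(), assoc["p"].to_numpy(), base=logp_base),
        index=assoc.index,
    )
    return ranksum_set_test(T, gene_sets)


# ---------------------------------------------------------------------------
# cis association


@dataclass
class CisResult:
    """Per-gene, per-variation cis calls with trait-level evidence."""

    evidence: pd.DataFrame        # index (gene, variation), columns per trait
    filters: pd.DataFrame         # directional-filter pass per (gene, variation)
    significant: pd.DataFrame     # per-trait boolean calls
    configuration: pd.Series      # per (gene, variation) label among 8 patterns
    thresholds: pd.DataFrame      # per (variation, trait) score cutoff + eFDR
    r2: pd.DataFrame = field(default_factory=pd.DataFrame)


def _cis_fit_gene(y: np.ndarray, V: np.ndarray, C: np.ndarray | None):
    """Regression of one trait on the gene's variations + covariates.

    Returns (betas, pvalues, r2_full, r2_drop) for the variation columns.
    """
    n = y.shape[0]
    base = [np.ones(n)]
    if C is not None:
        base.append(C)
    X = np.column_stack(base + [V])
    k = X.shape[1]
    nv = V.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - k
    sigma2 = float(resid @ resid) / dof
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_full = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    vb = beta[-nv:]
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv)[-nv:], 1e-300, None))
    t = vb / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    # reduced models for delta-R2
    r2_drop = np.empty(nv)
    for j in range(nv):
        keep = [c for c in range(X.shape[1]) if c != X.shape[1] - nv + j]
        Xr = X[:, keep]
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        r2_drop[j] = 1.0 - float(rr @ rr) / tss if tss > 0 else 0.0
    return vb, p, r2_full, np.clip(r2_full - r2_drop, 0.0, None)


_FILTER_RULES = {
    "cnv_lr": "positive",        # must be positively associated with all traits
    "methylation": "negative",   # must be negatively associated with all traits
    "cnv_baf": "consistent",     # consistent direction across traits
    "mutation": "consistent",
}


def _apply_filter(rule: str, betas: np.ndarray) -> bool:
    if rule == "positive":
        return bool(np.all(betas > 0))
    if rule == "negative":
        return bool(np.all(betas < 0))
    return bool(np.all(betas > 0) or np.all(betas < 0))


def _config_label(flags: dict) -> str:
    key = (flags.get("mrna", False), flags.get("protein", False),
           flags.get("phospho", False))
    return {
        (False, False, False): "none",
        (True, False, False): "mrna_only",
        (False, True, False): "protein_only",
        (False, False, True): "phospho_only",
        (True, True, False): "mrna_protein",
        (True, False, True): "mrna_phospho",
        (False, True, True): "protein_phospho",
        (True, True, True): "all_three",
    }[key]


def cis_assoc(
    variations: dict,
    traits: dict,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 100,
    efdr: float = 0.05,
    mutation_rate_threshold: float = 0.05,
    seed: int = 0,
) -> CisResult:
    """Cis association of each gene's DNA variations with its own mRNA,
    protein, and phosphopeptide traits.

    ``variations`` maps gene -> samples x variation-columns frame (subset
    of cnv_lr, cnv_baf, methylation, mutation); ``traits`` maps trait name
    (mrna/protein/phospho) -> genes x samples matrix. Mutation enters only
    for genes whose mutation rate exceeds ``mutation_rate_threshold``.

    Per (variation, trait) the evidence score is -log10(p) from the trait's
    regression; directional filters are applied (CNV-lr positive on all
    traits, methylation negative on all, baf/mutation direction-consistent)
    and the significance cutoff is calibrated to empirical FDR < ``efdr``
    by outcome-label permutations.
    """
    trait_names = list(traits)
    genes = [g for g in variations
             if all(g in traits[t].index for t in trait_names)]
    if len(genes) < 30:
        raise ValueError(f"cis_assoc requires >= 30 genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    samples = traits[trait_names[0]].columns
    C = covariates.loc[samples].to_numpy(dtype=float) if covariates is not None else None

    # normalized outcomes per trait
    Y = {t: {g: inverse_normal_transform(traits[t].loc[g, samples])
             for g in genes} for t in trait_names}

    def var_columns(g):
        V = variations[g].loc[samples]
        cols = list(V.columns)
        if "mutation" in cols:
            if V["mutation"].mean() <= mutation_rate_threshold:
                cols.remove("mutation")
        return V[cols], cols

    def run(perm_order=None):
        ev_rows, beta_rows, r2_rows = {}, {}, {}
        for g in genes:
            Vg, cols = var_columns(g)
            Vm = Vg.to_numpy(dtype=float)
            for t in trait_names:
                y = Y[t][g]
                if perm_order is not None:
                    y = y[perm_order]
                b, p, _, dr2 = _cis_fit_gene(y, Vm, C)
                for ci, cname in enumerate(cols):
                    ev_rows[(g, cname, t)] = -np.log10(max(p[ci], 1e-300))
                    beta_rows[(g, cname, t)] = b[ci]
                    r2_rows[(g, cname, t)] = dr2[ci]
        return ev_rows, beta_rows, r2_rows

    ev, betas, r2 = run()

    def to_frame(d):
        s = pd.Series(d)
        s.index = pd.MultiIndex.from_tuples(s.index, names=["gene", "variation", "trait"])
        return s.unstack("trait")

    ev_f = to_frame(ev)
    beta_f = to_frame(betas)
    r2_f = to_frame(r2)

    filt = pd.Series({
        (g, v): _apply_filter(_FILTER_RULES.get(v, "consistent"),
                              beta_f.loc[(g, v)].to_numpy(dtype=float))
        for (g, v) in ev_f.index
    })
    filt.index = ev_f.index

    # permutation null of evidence scores (filters applied to permuted fits too)
    variations_present = ev_f.index.get_level_values("variation").unique()
    null_scores = {(v, t): [] for v in variations_present for t in trait_names}
    n = len(samples)
    for _ in range(n_perm):
        order = rng.permutation(n)
        ev_p, beta_p, _ = run(order)
        evp_f = to_frame(ev_p)
        betap_f = to_frame(beta_p)
        filt_p = pd.Series({
            (g, v): _apply_filter(_FILTER_RULES.get(v, "consistent"),
                                  betap_f.loc[(g, v)].to_numpy(dtype=float))
            for (g, v) in evp_f.index
        })
        filt_p.index = evp_f.index
        for v in variations_present:
            sub = evp_f.xs(v, level="variation")
            keep = filt_p.xs(v, level="variation")
            for t in trait_names:
                vals = sub[t][keep.to_numpy()].to_numpy()
                null_scores[(v, t)].append(vals)

    thresholds = {}
    significant = pd.DataFrame(False, index=ev_f.index, columns=trait_names)
    for v in variations_present:
        obs_sub = ev_f.xs(v, level="variation")
        keep = filt.xs(v, level="variation").to_numpy()
        for t in trait_names:
            obs_vals = obs_sub[t].to_numpy()[keep]
            # the directional filters drop different genes per permutation,
            # so the null sets are ragged; average exceedances per permutation
            thr, e = _efdr_threshold_ragged(obs_vals, null_scores[(v, t)], efdr)
            thresholds[(v, t)] = (thr, e)
            gene_idx = obs_sub.index
            calls = pd.Series(False, index=gene_idx)
            calls[gene_idx[keep][obs_vals > thr]] = True
            for g in gene_idx:
                significant.loc[(g, v), t] = bool(calls[g])

    config = pd.Series({
        (g, v): _config_label({t: bool(significant.loc[(g, v), t]) for t in trait_names})
        for (g, v) in ev_f.index
    })
    config.index = ev_f.index
    thr_f = pd.DataFrame(
        {k: {"threshold": v[0], "efdr": v[1]} for k, v in thresholds.items()}
    ).T
    thr_f.index = pd.MultiIndex.from_tuples(thr_f.index, names=["variation", "trait"])
    return CisResult(
        evidence=ev_f, filters=filt.to_frame("passed"), significant=significant,
        configuration=config, thresholds=thr_f, r2=r2_f,
    )


def _efdr_threshold_ragged(obs: np.ndarray, null_list: list, level: float):
    obs = np.asarray(obs, float)
    if obs.size == 0:
        return np.inf, 0.0
    cand = np.unique(obs)
    thresholds = cand - np.spacing(np.abs(cand)) * 4
    n_perm = len(null_list)
    all_null = np.sort(np.concatenate([np.asarray(a, float) for a in null_list])) \
        if n_perm else np.array([])
    obs_sorted = np.sort(obs)
    curve = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        n_obs = obs_sorted.size - np.searchsorted(obs_sorted, t, side="right")
        n_null = (all_null.size - np.searchsorted(all_null, t, side="right")) / max(n_perm, 1)
        curve[i] = n_null / n_obs if n_obs else 0.0
    for i in range(len(curve) - 2, -1, -1):  # monotone non-increasing in T
        curve[i] = max(curve[i], curve[i + 1])
    ok = np.where(curve < level)[0]
    if ok.size == 0:
        return np.inf, 0.0
    return float(thresholds[ok[0]]), float(curve[ok[0]])


def r2_decomposition(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    variations: list,
) -> pd.Series:
    """Delta R-squared of each named design column: R2(full) minus R2 of
    the model refit without that column, clipped at zero."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y))] + [design[c].to_numpy(dtype=float)
                                             for c in design.columns])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design: columns {list(design.columns)}")
    tss = float(np.sum((y - y.mean()) ** 2))

    def r2_of(Xm):
        b, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ b
        return 1.0 - float(r @ r) / tss if tss > 0 else 0.0

    full = r2_of(X)
    out = {}
    for v in variations:
        j = list(design.columns).index(v) + 1
        Xr = np.delete(X, j, axis=1)
        out[v] = max(full - r2_of(Xr), 0.0)
    return pd.Series(out, name="delta_r2")


def clinical_multivariate(
    traits: pd.DataFrame,
    clinical: pd.DataFrame,
    numeric: list | None = None,
    report_threshold: float = 0.10,
) -> dict:
    """One multivariate regression per gene on all clinical covariates.

    Numeric covariates enter as-is; the rest are dummy-coded (first level
    dropped). P-values are BH-adjusted per covariate across genes. Returns
    the adjusted-p table and the per-covariate count of genes below the
    reporting threshold.
    """
    samples = traits.columns.intersection(clinical.index)
    cl = clinical.loc[samples]
    if numeric is None:
        numeric = [c for c in cl.columns if pd.api.types.is_numeric_dtype(cl[c])]
    parts = [cl[numeric].astype(float)]
    cat = [c for c in cl.columns if c not in numeric]
    if cat:
        parts.append(pd.get_dummies(cl[cat].astype(str), drop_first=True, dtype=float))
    Xdf = pd.concat(parts, axis=1)
    X = np.column_stack([np.ones(len(samples)), Xdf.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased, cols_so_far = [], [np.ones(len(samples))]
        for c in Xdf.columns:
            trial = np.column_stack(cols_so_far + [Xdf[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == len(cols_so_far):
                aliased.append(c)
            else:
                cols_so_far.append(Xdf[c].to_numpy(dtype=float))
        raise ValueError(f"rank-deficient design; aliased covariates: {aliased}")

    Y = traits[samples].T.to_numpy(dtype=float)
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    pvals = {}
    for j, c in enumerate(Xdf.columns, start=1):
        se = np.sqrt(np.clip(sigma2 * XtX_inv[j, j], 1e-300, None))
        t = beta[j] / se
        pvals[c] = 2.0 * sps.t.sf(np.abs(t), dof)
    p_df = pd.DataFrame(pvals, index=traits.index)
    adj = pd.DataFrame(np.column_stack([bh_adjust(p_df[c].to_numpy()) for c in p_df.columns]),
                       index=traits.index, columns=p_df.columns)
    counts = (adj < report_threshold).sum(axis=0)
    return {"p": p_df, "p_adj": adj, "counts": counts,
            "beta": pd.DataFrame(beta[1:].T, index=traits.index, columns=Xdf.columns)}
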