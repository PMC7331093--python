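"""mRNA-protein correlation analyses and cross-omic sample-alignment QC:
gene-wise and sample-wise Spearman profiles, covariate models on sample-wise
correlation, rank-based set enrichment, and detection of sample swaps."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, ranksum_set_test

__all__ = [
    "genewise_corr",
    "samplewise_corr",
    "corr_covariate_model",
    "rank_set_enrichment",
    "sample_alignment_check",
]


def _complete_cases(a: pd.DataFrame, b: pd.DataFrame):
    genes = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    if len(samples) < 5:
        raise ValueError(f"need >= 5 shared samples, got {len(samples)}")
    a = a.loc[genes, samples]
    b = b.loc[genes, samples]
    keep = a.notna().all(axis=1) & b.notna().all(axis=1)
    return a[keep], b[keep]


def genewise_corr(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    adj_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Spearman correlation across samples (complete-case genes),
    with BH-adjusted p and the significantly-positive flag at the given
    adjusted-p threshold."""
    a, b = _complete_cases(mrna, protein)
    rows = []
    for g in a.index:
        rho, p = sps.spearmanr(a.loc[g], b.loc[g])
        rows.append((g, rho, p))
    res = pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["significant_positive"] = (res["p_adj"] < adj_threshold) & (res["rho"] > 0)
    return res


def samplewise_corr(mrna: pd.DataFrame, protein: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Spearman correlation across shared complete-case genes,
    with tertile labels (high/middle/low) assigned by rank."""
    a, b = _complete_cases(mrna, protein)
    rows = []
    for s in a.columns:
        rho, p = sps.spearmanr(a[s], b[s])
        rows.append((s, rho, p))
    res = pd.DataFrame(rows, columns=["sample", "rho", "p"]).set_index("sample")
    ranks = res["rho"].rank(method="first")
    n = len(res)
    cut = np.ceil(ranks / (n / 3.0)).clip(1, 3)
    res["tertile"] = cut.map({1.0: "low", 2.0: "middle", 3.0: "high"})
    return res


def corr_covariate_model(
    sample_rho: pd.Series,
    covariates: pd.DataFrame,
    purity: pd.Series | None = None,
) -> pd.DataFrame:
    """Model per-sample correlation as a linear function of each covariate,
    univariately and (when purity is given) adjusted for purity.

    Constant covariates are skipped. Returns effect and p for both fits.
    """
    samples = sample_rho.index.intersection(covariates.index)
    if len(samples) < 10:
        raise ValueError("need >= 10 samples")
    y = sample_rho.loc[samples].to_numpy(dtype=float)
    rows = []
    for c in covariates.columns:
        x = covariates.loc[samples, c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        X1 = np.column_stack([np.ones(len(y)), x])
        b1, p1 = _ols_effect(X1, y, 1)
        b2 = p2 = np.nan
        if purity is not None:
            X2 = np.column_stack([np.ones(len(y)), x,
                                  purity.loc[samples].to_numpy(dtype=float)])
            b2, p2 = _ols_effect(X2, y, 1)
        rows.append((c, b1, p1, b2, p2))
    return pd.DataFrame(
        rows, columns=["covariate", "beta", "p", "beta_adjusted", "p_adjusted"]
    ).set_index("covariate")


def _ols_effect(X: np.ndarray, y: np.ndarray, col: int):
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(max(sigma2 * XtX_inv[col, col], 1e-300))
    t = beta[col] / se
    return float(beta[col]), float(2 * sps.t.sf(abs(t), n - k))


def rank_set_enrichment(scores: pd.Series, gene_sets: dict) -> pd.DataFrame:
    """Two-sided rank-sum enrichment of gene sets on a per-gene score list
    (e.g., mRNA-protein correlations), BH-adjusted with directions."""
    return ranksum_set_test(scores, gene_sets)


def sample_alignment_check(
    a: pd.DataFrame,
    b: pd.DataFrame,
    n_top: int = 500,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Cross-data-type sample alignment QC.

    Selects the top ``n_top`` genes by gene-wise correlation between the
    two data types (under the nominal pairing), rank-transforms each gene's
    values per matrix, and scores each sample by the Spearman similarity of
    its rank profiles. A sample is flagged when the z-score of its
    self-similarity against the cross-pair distribution falls below
    ``z_threshold``.
    """
    import warnings
    genes = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    if len(samples) < 20:
        raise ValueError(f"need >= 20 shared samples, got {len(samples)}")
    if len(genes) < n_top:
        warnings.warn(
            f"only {len(genes)} shared genes (< {n_top}); using all", stacklevel=2)
        n_top = len(genes)
    n = len(samples)
    # per-gene rank profiles across samples
    RA = a.loc[genes, samples].rank(axis=1).to_numpy(dtype=float)
    RB = b.loc[genes, samples].rank(axis=1).to_numpy(dtype=float)

    def gene_corr(exclude: int) -> np.ndarray:
        """Per-gene Pearson correlation of the rank profiles, leaving one
        sample column out so gene selection never sees the scored sample."""
        mask = np.ones(n, bool)
        mask[exclude] = False
        x = RA[:, mask]
        y = RB[:, mask]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (xc * yc).sum(axis=1) / denom, 0.0)

    rows = []
    for i, s in enumerate(samples):
        # top genes chosen without sample i (avoids selection leaking a
        # spurious self-similarity into null data)
        top_idx = np.argsort(gene_corr(i))[::-1][:n_top]
        prof_a = RA[top_idx, i]
        scores = np.array([
            sps.spearmanr(prof_a, RB[top_idx, j])[0] for j in range(n)
        ])
        self_score = scores[i]
        cross = np.delete(scores, i)
        mu, sd = float(cross.mean()), float(cross.std(ddof=1))
        z = (self_score - mu) / sd if sd > 0 else np.inf
        # mismatch when the self score does not stand out from the cross
        # scores, or when some other sample's profile matches better
        flagged = bool(z < z_threshold or self_score < cross.max())
        rows.append((s, float(self_score), float(z), flagged))
    return pd.DataFrame(
        rows, columns=["sample", "self_similarity", "z", "flagged"]
    ).set_index("sample")
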