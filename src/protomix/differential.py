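"""Tumor-vs-NAT differential expression: bulk rank-sum testing, a
purity-aware two-component mixture model with permutation FDR, and
anatomic-region allocation of NAT samples.

The mixture model treats the observed bulk abundance of gene j in sample i
as  X_ij = pi_i * y_ij + (1 - pi_i) * z_ij  with y (pure tissue) and z
(stroma/immune) Gaussian and purity pi fixed and known, so marginally

    X_ij ~ Normal(pi_i*muY + (1-pi_i)*muZ, pi_i^2*sigY^2 + (1-pi_i)^2*sigZ^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .stats import bh_adjust, efdr_threshold

__all__ = [
    "wilcoxon_diff",
    "PurityModelFit",
    "fit_purity_model",
    "purity_diff",
    "allocate_nat_regions",
]


def wilcoxon_diff(
    tumor: pd.DataFrame,
    nat: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per feature on log2 matrices.

    Significant features have |log2 fold change| >= log2(fc_threshold) and
    BH-adjusted p < fdr_threshold. Features with an all-missing group are
    excluded.
    """
    features = tumor.index.intersection(nat.index)
    if tumor.shape[1] < 3 or nat.shape[1] < 3:
        raise ValueError("need >= 3 samples per group")
    rows = []
    for f in features:
        a = tumor.loc[f].dropna().to_numpy(dtype=float)
        b = nat.loc[f].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((f, float(a.mean() - b.mean()), float(stat), float(p)))
    res = pd.DataFrame(rows, columns=["feature", "log2fc", "statistic", "p"]).set_index("feature")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = (
        (res["log2fc"].abs() >= np.log2(fc_threshold))
        & (res["p_adj"] < fdr_threshold)
    )
    return res


# ---------------------------------------------------------------------------
# purity mixture model


@dataclass
class PurityModelFit:
    """Per-feature mixture parameters for one tissue class, plus the
    feature centering/scale used for the z-transform (needed to express
    z-scale mean differences back on the log2 scale)."""

    params: pd.DataFrame          # columns mu_pure, mu_stroma, sd_pure, sd_stroma
    purity: pd.Series
    feature_center: pd.Series
    feature_scale: pd.Series
    stroma_identified: bool = True


def _fit_one_feature(x: np.ndarray, pi: np.ndarray, polish: bool,
                     n_iter: int = 25) -> tuple[float, float, float, float]:
    """Moment/GLS iteration (optionally polished by bounded quasi-Newton)
    for one feature's marginal likelihood."""
    A = np.column_stack([pi, 1.0 - pi])
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ beta
    v = max(float(np.var(resid)), 1e-8)
    s2 = np.array([v, v])
    V = np.column_stack([pi ** 2, (1.0 - pi) ** 2])
    for _ in range(n_iter):
        var_i = np.clip(V @ s2, 1e-10, None)
        w = 1.0 / var_i
        WA = A * w[:, None]
        beta = np.linalg.solve(A.T @ WA, WA.T @ x)
        resid = x - A @ beta
        s2_new, _ = optimize.nnls(V, resid ** 2)
        s2_new = np.clip(s2_new, 1e-8, None)
        if np.allclose(s2_new, s2, rtol=1e-6) :
            s2 = s2_new
            break
        s2 = s2_new
    if polish:
        def nll(theta):
            muY, muZ, lsY, lsZ = theta
            var_i = pi ** 2 * np.exp(2 * lsY) + (1 - pi) ** 2 * np.exp(2 * lsZ)
            mean_i = pi * muY + (1 - pi) * muZ
            return 0.5 * np.sum(np.log(2 * np.pi * var_i) + (x - mean_i) ** 2 / var_i)

        x0 = np.array([beta[0], beta[1], 0.5 * np.log(s2[0]), 0.5 * np.log(s2[1])])
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(None, None), (None, None), (-8, 4), (-8, 4)])
        if res.success and res.fun <= nll(x0):
            beta = res.x[:2]
            s2 = np.exp(2 * res.x[2:])
    # asymptotic SEs of the means from the final weighted design
    var_i = np.clip(V @ s2, 1e-10, None)
    info = A.T @ (A / var_i[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return (float(beta[0]), float(beta[1]), float(np.sqrt(s2[0])),
            float(np.sqrt(s2[1])), float(se[0]), float(se[1]))


def fit_purity_model(
    matrix: pd.DataFrame,
    purity: pd.Series,
    zscore: bool = True,
    center: pd.Series | None = None,
    scale: pd.Series | None = None,
    polish: bool = True,
) -> PurityModelFit:
    """Fit (mu_pure, mu_stroma, sd_pure, sd_stroma) per feature for one
    tissue class by maximizing the marginal Gaussian likelihood.

    Features are z-scored across samples unless pre-computed ``center`` /
    ``scale`` are supplied (use those to share the transform across tissue
    classes). If all samples share one purity the two means are not
    separable: at purity ~1 ``mu_pure`` is the sample mean and the stroma
    side is flagged unidentified, otherwise an error is raised.
    """
    samples = matrix.columns
    pi = purity.loc[samples].to_numpy(dtype=float)
    if np.any((pi <= 0) | (pi >= 1)) and not np.allclose(pi, 1.0):
        if np.any((pi <= 0) | (pi > 1)):
            raise ValueError("purity values must lie in (0, 1]")
    if zscore and center is None:
        center = matrix.mean(axis=1)
        scale = matrix.std(axis=1, ddof=1).replace(0, np.nan)
    if center is not None:
        Z = matrix.sub(center, axis=0).div(scale, axis=0)
    else:
        Z = matrix
        center = pd.Series(0.0, index=matrix.index)
        scale = pd.Series(1.0, index=matrix.index)

    if float(np.ptp(pi)) < 1e-12:
        if np.allclose(pi, 1.0):
            params = pd.DataFrame({
                "mu_pure": Z.mean(axis=1),
                "mu_stroma": np.nan,
                "sd_pure": Z.std(axis=1, ddof=1),
                "sd_stroma": np.nan,
                "se_pure": Z.std(axis=1, ddof=1) / np.sqrt(Z.shape[1]),
                "se_stroma": np.nan,
            })
            return PurityModelFit(params, purity.loc[samples], center, scale,
                                  stroma_identified=False)
        raise ValueError(
            f"constant purity ({pi[0]:.3f}) for all samples: mixture means "
            f"unidentifiable for features {list(matrix.index[:3])}..."
        )

    rows = {}
    for f in Z.index:
        x = Z.loc[f].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 4:
            rows[f] = (np.nan,) * 6
            continue
        rows[f] = _fit_one_feature(x[ok], pi[ok], polish)
    params = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["mu_pure", "mu_stroma", "sd_pure", "sd_stroma",
                 "se_pure", "se_stroma"],
    )
    params.index.name = matrix.index.name
    return PurityModelFit(params, purity.loc[samples], center, scale)


def purity_diff(
    matrix: pd.DataFrame,
    purity: pd.Series,
    tissue: pd.Series,
    n_perm: int = 200,
    fdr: float = 0.10,
    fc_threshold: float = 2.0,
    seed: int = 0,
    polish: bool = False,
) -> pd.DataFrame:
    """Purity-deconvolved tumor-vs-NAT differential test.

    Fits the mixture per tissue class, takes the pure-component mean
    difference per feature, and calibrates significance against a null
    obtained by refitting under tumor/NAT label permutations. A feature is
    significant when it passes the permutation FDR cut AND its mean
    difference, mapped back to the log2 scale, exceeds log2(fc_threshold).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    import warnings
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} is small; FDR estimates will be noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    tissue = tissue.loc[matrix.columns]
    center = matrix.mean(axis=1)
    scale = matrix.std(axis=1, ddof=1).replace(0, np.nan)

    def delta_for(labels: pd.Series) -> pd.Series:
        t_cols = labels.index[labels == "T"]
        n_cols = labels.index[labels == "N"]
        fit_t = fit_purity_model(matrix[t_cols], purity, zscore=False,
                                 center=center, scale=scale, polish=polish)
        fit_n = fit_purity_model(matrix[n_cols], purity, zscore=False,
                                 center=center, scale=scale, polish=polish)
        return fit_t.params["mu_pure"] - fit_n.params["mu_pure"]

    obs = delta_for(tissue)
    null = np.empty((n_perm, len(obs)))
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(tissue.to_numpy()), index=tissue.index)
        null[b] = delta_for(perm).to_numpy()

    # back to log2 scale: z-scale differences scaled by the pre-z SD
    sd = scale.loc[obs.index].to_numpy(dtype=float)
    obs_log2 = np.abs(obs.to_numpy()) * sd
    null_log2 = np.abs(null) * sd[None, :]
    thr, efdr = efdr_threshold(obs_log2, null_log2, level=fdr)

    res = pd.DataFrame({
        "delta_z": obs,
        "delta_log2": obs.to_numpy() * sd,
        "abs_delta_log2": obs_log2,
    })
    res["threshold"] = thr
    res["efdr_at_threshold"] = efdr
    res["significant"] = (
        (obs_log2 > thr) & (obs_log2 >= np.log2(fc_threshold))
    )
    return res


def allocate_nat_regions(
    matrix: pd.DataFrame,
    signatures: dict,
    region_order: list | None = None,
) -> pd.DataFrame:
    """Allocate each sample to the anatomic region with the highest mean
    z-score over the region's signature genes.

    Genes are z-scored across samples first. Exact ties go to the first
    region in ``region_order`` (default: insertion order of ``signatures``)
    and are flagged in the ``tie`` column; samples whose profiles overlap
    no signature are left unassigned.
    """
    order = list(region_order) if region_order is not None else list(signatures)
    z = matrix.sub(matrix.mean(axis=1), axis=0).div(
        matrix.std(axis=1, ddof=1).replace(0, np.nan), axis=0)
    scores = {}
    for region in order:
        genes = matrix.index.intersection(pd.Index(signatures[region]))
        if len(genes) == 0:
            continue
        scores[region] = z.loc[genes].mean(axis=0)
    if not scores:
        raise ValueError("no signature overlaps the measured genes")
    score_df = pd.DataFrame(scores)[[r for r in order if r in scores]]
    best = score_df.idxmax(axis=1)
    maxval = score_df.max(axis=1)
    tie = (score_df.eq(maxval, axis=0).sum(axis=1) > 1)
    out = pd.DataFrame({"region": best, "score": maxval, "tie": tie})
    out.loc[score_df.isna().all(axis=1), "region"] = None
    return out
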