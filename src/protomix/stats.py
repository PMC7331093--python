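"""Shared statistical primitives: BH adjustment, empirical-FDR thresholding,
rank-based inverse-normal transform, and the signed rank-sum pathway scorer."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bh_adjust",
    "efdr_curve",
    "efdr_threshold",
    "inverse_normal_transform",
    "signed_logp_scores",
    "ranksum_set_test",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone-enforced).

    NaN entries are ignored in the ranking and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="mergesort")
    ranked = pm[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def efdr_curve(observed: np.ndarray, null: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Empirical FDR at each threshold.

    eFDR(T) = (average count of null statistics > T per permutation)
              / (count of observed statistics > T).

    Parameters
    ----------
    observed : 1-D array of observed statistics (larger = more significant).
    null : 2-D array (n_permutations x n_features) of permuted statistics,
        or 1-D array treated as a single permutation.
    thresholds : candidate cutoffs.
    """
    observed = np.asarray(observed, float)
    null = np.atleast_2d(np.asarray(null, float))
    n_perm = null.shape[0]
    obs_sorted = np.sort(observed[np.isfinite(observed)])
    null_flat = np.sort(null[np.isfinite(null)])
    thresholds = np.asarray(thresholds, float)
    out = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        n_obs = obs_sorted.size - np.searchsorted(obs_sorted, t, side="right")
        n_null = (null_flat.size - np.searchsorted(null_flat, t, side="right")) / n_perm
        out[i] = n_null / n_obs if n_obs > 0 else 0.0
    # enforce monotone non-increasing eFDR in T (conservative smoothing):
    # raising the cutoff can only tighten the call set
    order = np.argsort(thresholds)
    smoothed = out[order]
    for i in range(len(smoothed) - 2, -1, -1):
        smoothed[i] = max(smoothed[i], smoothed[i + 1])
    res = np.empty_like(out)
    res[order] = smoothed
    return res


def efdr_threshold(observed, null, level: float = 0.10):
    """Smallest threshold T (searched on the observed statistics) with
    empirical FDR below ``level``.

    Returns ``(threshold, efdr_at_threshold)``. If no observed statistic
    attains the level, returns ``(inf, 0.0)`` (nothing is called).
    """
    observed = np.asarray(observed, float)
    finite = observed[np.isfinite(observed)]
    if finite.size == 0:
        return np.inf, 0.0
    # candidate cutoffs just below each observed statistic so that the
    # statistic itself passes "|t| > T"
    cand = np.unique(finite)
    eps = np.spacing(np.abs(cand)) * 4
    thresholds = cand - eps
    curve = efdr_curve(observed, null, thresholds)
    ok = np.where(curve < level)[0]
    if ok.size == 0:
        return np.inf, 0.0
    idx = ok[0]
    return thresholds[idx], curve[idx]


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform (ties averaged, NaN preserved)."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = mask.sum()
    if n == 0:
        return out
    ranks = sps.rankdata(x[mask], method="average")
    out[mask] = sps.norm.ppf((ranks - 0.5) / n)
    return out


def signed_logp_scores(beta, pvalues, base: str = "e") -> np.ndarray:
    """Per-gene association summary T = -sign(beta) * log(p).

    Large positive T: the feature is strongly positively associated.
    """
    beta = np.asarray(beta, float)
    p = np.asarray(pvalues, float)
    log = np.log10 if base == "10" else np.log
    with np.errstate(divide="ignore"):
        return -np.sign(beta) * log(np.clip(p, 1e-300, 1.0))


def ranksum_set_test(scores: pd.Series, gene_sets: dict, min_size: int = 2) -> pd.DataFrame:
    """Two-sided rank-sum of in-set vs out-of-set scores for each set.

    Returns a frame with statistic, p, BH-adjusted p, direction ('up' when
    the in-set median exceeds the out-set median) and the signed
    ``log10`` score = +/- log10(adjusted p).
    """
    scores = scores.dropna()
    rows = []
    for name, members in gene_sets.items():
        inset = scores.index.intersection(pd.Index(members))
        if len(inset) < min_size:
            continue
        t_in = scores.loc[inset].to_numpy()
        t_out = scores.drop(inset).to_numpy()
        if t_out.size == 0:
            continue
        stat, p = sps.mannwhitneyu(t_in, t_out, alternative="two-sided")
        direction = "up" if np.median(t_in) > np.median(t_out) else "down"
        rows.append((name, len(inset), stat, p, direction))
    if not rows:
        return pd.DataFrame(
            columns=["set", "n_members", "statistic", "p", "p_adj", "direction", "score"]
        ).set_index("set")
    df = pd.DataFrame(rows, columns=["set", "n_members", "statistic", "p", "direction"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    sign = np.where(df["direction"] == "up", 1.0, -1.0)
    df["score"] = sign * -np.log10(np.clip(df["p_adj"].to_numpy(), 1e-300, 1.0))
    return df.set_index("set")[["n_members", "statistic", "p", "p_adj", "direction", "score"]]
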