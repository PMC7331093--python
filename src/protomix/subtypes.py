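"""Consensus-clustering engine (subsampled PAM or hierarchical base) plus
methylation-marker subtype classification and subtype/feature association
tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ConsensusResult",
    "pam_cluster",
    "consensus_cluster",
    "cimp_classify",
    "subtype_association",
]


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame     # samples x samples co-clustering frequency
    labels: pd.Series
    k: int
    repeats: int
    fraction: float
    base: str
    seed: int


def pam_cluster(D: np.ndarray, k: int) -> np.ndarray:
    """Deterministic partitioning around medoids on a distance matrix.

    BUILD initialization (greedy medoid selection) followed by alternating
    assignment / per-cluster medoid updates until stable.
    """
    n = D.shape[0]
    if k > n:
        raise ValueError("k exceeds number of points")
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = np.min(D[:, medoids], axis=1)
        gains = np.array([
            np.sum(np.maximum(current - D[:, c], 0.0)) if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(100):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for ci in range(k):
            members = np.where(assign == ci)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[ci] = members[int(np.argmin(within))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _base_labels(X: np.ndarray, k: int, base: str) -> np.ndarray:
    """Cluster rows of X into k groups."""
    if base == "pam":
        D = squareform(pdist(X, metric="euclidean"))
        return pam_cluster(D, k)
    if base == "hierarchical":
        Z = linkage(X, method="complete", metric="euclidean")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown base algorithm {base!r}")


def consensus_cluster(
    matrix: pd.DataFrame,
    k: int,
    repeats: int = 200,
    fraction: float = 0.8,
    base: str = "pam",
    zscore: bool = False,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering over random subsamples of the samples.

    ``matrix`` is features x samples. Per repeat, ``fraction`` of the
    samples are drawn without replacement and clustered with the base
    algorithm; consensus(i, j) is the co-clustering count over the
    co-sampling count. Final labels come from complete-linkage hierarchical
    clustering of 1 - consensus cut into k groups.
    """
    samples = list(matrix.columns)
    n = len(samples)
    if n < k * 5:
        raise ValueError(f"need >= {k * 5} samples for k={k}, got {n}")
    X = matrix.to_numpy(dtype=float).T
    if zscore:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    rng = np.random.default_rng(seed)
    m = max(k, int(round(fraction * n)))
    together = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    for _ in range(repeats):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels = _base_labels(X[idx], k, base)
        co_sampled[np.ix_(idx, idx)] += 1.0
        for c in np.unique(labels):
            members = idx[labels == c]
            together[np.ix_(members, members)] += 1.0
    with np.errstate(invalid="ignore"):
        consensus = np.where(co_sampled > 0, together / co_sampled, np.nan)
    if np.isnan(consensus).any():
        warnings.warn("some sample pairs were never co-sampled", stacklevel=2)
    cfill = np.nan_to_num(consensus, nan=0.0)
    dist = 1.0 - cfill
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        labels=pd.Series(labels, index=samples, name="cluster"),
        k=k, repeats=repeats, fraction=fraction, base=base, seed=seed,
    )


def cimp_classify(beta: pd.DataFrame, marker_probes=None) -> pd.Series:
    """Split samples into hypermethylated (CIMP+) and CIMP- groups.

    Hierarchical clustering (Euclidean distance, complete linkage, no
    scaling) of the marker-probe beta values, cut into two clusters; the
    cluster with the higher mean beta over the markers is labeled CIMP+.
    """
    if marker_probes is not None:
        probes = beta.index.intersection(pd.Index(marker_probes))
        if len(probes) == 0:
            raise ValueError("no marker probes measured")
        beta = beta.loc[probes]
    beta = beta.dropna(how="all")
    if beta.empty:
        raise ValueError("all marker probes missing")
    if beta.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = beta.to_numpy(dtype=float).T
    Z = linkage(X, method="complete", metric="euclidean")
    if Z[-1, 2] == 0.0:  # all samples identical: no meaningful 2-way cut
        raise ValueError("degenerate input: cannot split identical samples into 2 clusters")
    labels = fcluster(Z, t=2, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate input: cannot split identical samples into 2 clusters")
    means = {c: X[labels == c].mean() for c in np.unique(labels)}
    pos = max(means, key=means.get)
    out = pd.Series(np.where(labels == pos, "CIMP+", "CIMP-"), index=beta.columns,
                    name="cimp")
    return out


def subtype_association(labels: pd.Series, features: pd.DataFrame) -> pd.DataFrame:
    """Chi-square test of independence between cluster labels and each
    categorical/binary feature.

    Degenerate margins (single level) are skipped; a warning column counts
    expected cells below 5.
    """
    samples = labels.index.intersection(features.index)
    rows = []
    for c in features.columns:
        tab = pd.crosstab(labels.loc[samples], features.loc[samples, c])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        stat, p, dof, expected = sps.chi2_contingency(tab, correction=False)
        rows.append((c, float(stat), float(p), int(dof),
                     int((expected < 5).sum())))
    return pd.DataFrame(
        rows, columns=["feature", "chi2", "p", "dof", "n_low_expected"]
    ).set_index("feature")
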