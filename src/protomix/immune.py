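"""Immune subtype discovery on cell-type score matrices, per-group
indicator-regression differentials, combined-z signature scores, one-vs-rest
marker selection, and the two-score transfer classifier for external
cohorts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .subtypes import ConsensusResult, consensus_cluster

__all__ = [
    "immune_group",
    "group_differential",
    "combined_z",
    "select_group_markers",
    "TransferModel",
    "transfer_classify",
]


def immune_group(
    cell_scores: pd.DataFrame,
    k: int = 6,
    repeats: int = 200,
    fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples in cell-type score space (PAM base,
    80% subsampling)."""
    return consensus_cluster(
        cell_scores, k=k, repeats=repeats, fraction=fraction, base="pam", seed=seed
    )


def group_differential(matrix: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """No-intercept indicator regression of each z-scored feature on group
    membership: X_ij = sum_k beta_kj * 1(i in group k) + eps.

    beta_kj is exactly the group-k mean of the z-scored feature; p-values
    test beta = 0 and are BH-adjusted across features within each group.
    Constant features are dropped; singleton groups are skipped with a
    warning.
    """
    samples = matrix.columns.intersection(labels.index)
    lab = labels.loc[samples]
    groups = [g for g in pd.unique(lab)]
    keep_groups = []
    for g in groups:
        if (lab == g).sum() < 2:
            warnings.warn(f"singleton group {g!r} skipped", stacklevel=2)
        else:
            keep_groups.append(g)
    sd = matrix[samples].std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) dropped", stacklevel=2)
    M = matrix.loc[~const, samples]
    Z = M.sub(M.mean(axis=1), axis=0).div(M.std(axis=1, ddof=1), axis=0)

    frames = []
    n = len(samples)
    k = len(keep_groups)
    # residual variance from the full indicator model
    fitted = pd.DataFrame(0.0, index=Z.index, columns=samples)
    betas = {}
    for g in keep_groups:
        cols = lab.index[lab == g]
        betas[g] = Z[cols].mean(axis=1)
        fitted[cols] = np.broadcast_to(
            betas[g].to_numpy()[:, None], (len(Z), len(cols)))
    resid = Z - fitted
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=1) / dof
    for g in keep_groups:
        n_g = int((lab == g).sum())
        se = np.sqrt(sigma2 / n_g)
        t = betas[g] / se
        p = 2.0 * sps.t.sf(np.abs(t), dof)
        frames.append(pd.DataFrame({
            "group": g, "beta": betas[g], "t": t, "p": p,
            "p_adj": bh_adjust(p),
        }))
    out = pd.concat(frames)
    out.index.name = "feature"
    return out.reset_index().set_index(["feature", "group"])


def combined_z(matrix: pd.DataFrame, genes) -> pd.Series:
    """Per-sample combined z-score of a gene set: z-score each member gene
    across samples, then sum and divide by sqrt(number of measured
    members)."""
    members = matrix.index.intersection(pd.Index(genes))
    if len(members) == 0:
        raise ValueError("gene set has no measured members")
    sub = matrix.loc[members]
    z = sub.sub(sub.mean(axis=1), axis=0).div(
        sub.std(axis=1, ddof=1).replace(0, np.nan), axis=0)
    return z.sum(axis=0, skipna=True) / np.sqrt(len(members))


def select_group_markers(
    expression: pd.DataFrame,
    labels: pd.Series,
    fdr: float = 0.10,
    lfc: float = 1.0,
) -> dict:
    """One-vs-rest marker genes per group: Welch t-test with BH adjustment;
    a gene qualifies with adjusted p below ``fdr`` and log fold change
    strictly greater than ``lfc``.

    Returns ``{"panel": union-of-markers, "per_group": {group: genes}}``.
    """
    samples = expression.columns.intersection(labels.index)
    lab = labels.loc[samples]
    per_group = {}
    for g in pd.unique(lab):
        inside = lab.index[lab == g]
        outside = lab.index[lab != g]
        a = expression[inside]
        b = expression[outside]
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
        delta = a.mean(axis=1) - b.mean(axis=1)
        q = bh_adjust(p)
        sel = expression.index[(q < fdr) & (delta.to_numpy() > lfc)]
        per_group[g] = list(sel)
        if len(sel) == 0:
            warnings.warn(f"no markers found for group {g!r}", stacklevel=2)
    panel = sorted(set().union(*per_group.values())) if per_group else []
    return {"panel": panel, "per_group": per_group}


@dataclass
class TransferModel:
    """Weights and reference expression panel backing the two-score
    transfer classifier."""

    weights: pd.DataFrame        # panel genes x groups: weight vector W_i
    reference: pd.DataFrame      # panel genes x training samples
    groups: pd.Series            # training sample -> group

    @classmethod
    def from_training(cls, expression: pd.DataFrame, labels: pd.Series,
                      panel=None) -> "TransferModel":
        """Fallback trainer: the weight vector of a group is the centroid
        of the z-scored expression of its training samples."""
        genes = expression.index if panel is None \
            else expression.index.intersection(pd.Index(panel))
        sub = expression.loc[genes]
        z = sub.sub(sub.mean(axis=1), axis=0).div(
            sub.std(axis=1, ddof=1).replace(0, np.nan), axis=0)
        samples = sub.columns.intersection(labels.index)
        w = {g: z[labels.index[labels == g].intersection(samples)].mean(axis=1)
             for g in pd.unique(labels.loc[samples])}
        return cls(weights=pd.DataFrame(w), reference=sub[samples],
                   groups=labels.loc[samples])


def _unit_normalize(values: np.ndarray) -> np.ndarray:
    """Subtract the lowest value, then divide by the maximum of the shifted
    values so the range is exactly [0, 1]."""
    if not np.isfinite(values).any():
        return values
    shifted = values - np.nanmin(values)
    mx = np.nanmax(shifted)
    return shifted / mx if mx > 0 else np.zeros_like(shifted)


def transfer_classify(
    model: TransferModel,
    external: pd.DataFrame,
    method: str = "spearman",
    min_panel_coverage: float = 0.8,
) -> pd.DataFrame:
    """Assign external samples to immune groups by two averaged scores.

    Score 1 (Z): correlation between each group's weight vector and the
    sample's expression over the panel, unit-normalized. Score 2 (Q):
    correlations to each training sample, unit-normalized within group,
    then averaged per group. Final score X = (Z + Q) / 2; the argmax group
    is assigned (ties to the earlier group in the model's column order).
    """
    corr = {"spearman": lambda u, v: sps.spearmanr(u, v)[0],
            "pearson": lambda u, v: sps.pearsonr(u, v)[0]}[method]
    panel = model.weights.index
    shared = panel.intersection(external.index)
    if len(shared) < min_panel_coverage * len(panel):
        warnings.warn(
            f"external matrix covers only {len(shared)}/{len(panel)} panel genes",
            stacklevel=2)
    W = model.weights.loc[shared]
    R = model.reference.loc[shared]
    E = external.loc[shared]
    groups = list(model.weights.columns)
    samples = list(external.columns)

    Z = np.full((len(groups), len(samples)), np.nan)
    unassigned = []
    for kx, s in enumerate(samples):
        x = E[s].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            unassigned.append(s)
            continue
        for gi, g in enumerate(groups):
            Z[gi, kx] = corr(W[g].to_numpy(dtype=float), x)
    Z = _unit_normalize(Z)

    S = np.full((R.shape[1], len(samples)), np.nan)
    for kx, s in enumerate(samples):
        if s in unassigned:
            continue
        x = E[s].to_numpy(dtype=float)
        for si, ts in enumerate(R.columns):
            S[si, kx] = corr(R[ts].to_numpy(dtype=float), x)
    Q = np.full((len(groups), len(samples)), np.nan)
    for gi, g in enumerate(groups):
        rows = [si for si, ts in enumerate(R.columns) if model.groups[ts] == g]
        block = _unit_normalize(S[rows, :])
        Q[gi] = np.nanmean(block, axis=0)

    X = (Z + Q) / 2.0
    assign = []
    for kx, s in enumerate(samples):
        if s in unassigned or np.all(np.isnan(X[:, kx])):
            assign.append(None)
            continue
        assign.append(groups[int(np.nanargmax(X[:, kx]))])
    out = pd.DataFrame(X.T, index=samples, columns=[f"score_{g}" for g in groups])
    for gi, g in enumerate(groups):
        out[f"z_{g}"] = Z[gi]
        out[f"q_{g}"] = Q[gi]
    out["group"] = assign
    return out
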