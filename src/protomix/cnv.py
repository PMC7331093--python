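"""Copy-number analysis from binned LR/BAF tracks: GC correction, joint
binary segmentation of LR and mirrored BAF, purity/ploidy grid search with
integer state assignment, arm-level event calling, and genome-instability
classification.

Expected values under purity p for a segment with total copy C and minor
allele count K:

    E[lr]  = log2((p*C + 2(1-p)) / 2)        (diploid-normal reference)
    E[baf] = (p*K + (1-p)) / (p*C + 2(1-p))
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthetic import expected_baf, expected_lr

__all__ = [
    "gc_correct",
    "segment_vector",
    "joint_segment",
    "PloidySolution",
    "fit_purity_ploidy",
    "arm_events",
    "genome_instability",
]


# ---------------------------------------------------------------------------
# GC correction


def gc_correct(
    track: pd.DataFrame,
    gc_range: tuple[float, float] = (0.3, 0.7),
    span: float = 0.5,
    min_bins: int = 100,
) -> pd.DataFrame:
    """Remove the GC trend from LR by weighted LOESS smoothing.

    The trend is fit on mappable bins with GC inside ``gc_range`` and
    applied to all bins (out-of-range bins are corrected using the boundary
    fit). The median LR is preserved.
    """
    mappable = track["mappable"].astype(bool) if "mappable" in track.columns \
        else pd.Series(True, index=track.index)
    in_range = mappable & track["gc"].between(*gc_range) & track["lr"].notna()
    if in_range.sum() < min_bins:
        raise ValueError(
            f"gc_correct needs >= {min_bins} mappable bins with GC in "
            f"{gc_range}, got {int(in_range.sum())}"
        )
    fit = lowess(
        track.loc[in_range, "lr"].to_numpy(),
        track.loc[in_range, "gc"].to_numpy(),
        frac=span,
        return_sorted=True,
    )
    # collapse duplicate gc values for interpolation
    xs, idx = np.unique(fit[:, 0], return_index=True)
    ys = fit[:, 1][idx]
    trend = np.interp(track["gc"].to_numpy(), xs, ys)
    out = track.copy()
    before = float(np.nanmedian(out["lr"]))
    out["lr"] = out["lr"] - trend
    out["lr"] = out["lr"] + (before - float(np.nanmedian(out["lr"])))
    return out


# ---------------------------------------------------------------------------
# segmentation


def _max_t_split(x: np.ndarray, trim: float, min_width: int):
    """Best binary split of x by two-sample t statistic; returns (idx, |t|).

    The pooled standard deviation is estimated from trimmed values so a few
    outlier bins do not mask a change point.
    """
    n = x.size
    if n < 2 * min_width:
        return None, 0.0
    lo_q, hi_q = np.quantile(x, [trim, 1.0 - trim])
    xt = x[(x >= lo_q) & (x <= hi_q)]
    sd = xt.std(ddof=1) if xt.size > 1 else x.std(ddof=1)
    sd = max(sd, 1e-8)
    cs = np.cumsum(x)
    total = cs[-1]
    ks = np.arange(min_width, n - min_width + 1)
    mean_l = cs[ks - 1] / ks
    mean_r = (total - cs[ks - 1]) / (n - ks)
    t = np.abs(mean_l - mean_r) / (sd * np.sqrt(1.0 / ks + 1.0 / (n - ks)))
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def segment_vector(
    x: np.ndarray,
    alpha: float = 0.01,
    trim: float = 0.025,
    n_perm: int = 100,
    min_width: int = 3,
    rng: np.random.Generator | None = None,
) -> list:
    """Recursive binary segmentation with a permutation p-value.

    Returns sorted interior breakpoint indices (a breakpoint at k splits
    x[:k] from x[k:]). A split is accepted when its max-|t| statistic beats
    ``alpha`` against within-segment permutations.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    breakpoints: list = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        k, t_obs = _max_t_split(seg, trim, min_width)
        if k is None or t_obs == 0.0:
            return
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(seg)
            _, t_p = _max_t_split(perm, trim, min_width)
            if t_p >= t_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_perm)
        if p <= alpha:
            breakpoints.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, x.size)
    return sorted(breakpoints)


def _mirrored(baf: np.ndarray) -> np.ndarray:
    return np.maximum(baf, 1.0 - baf)


def joint_segment(
    track: pd.DataFrame,
    alpha: float = 0.01,
    trim: float = 0.025,
    n_perm: int = 100,
    tol_lr: float = 0.1,
    tol_baf: float = 0.05,
    min_width: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Jointly segment LR and mirrored BAF per chromosome.

    Candidate breakpoints are the union of the two channels' binary
    segmentations; adjacent segments with similar LR and mirrored-BAF means
    are then merged iteratively, shortest segment first.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if len(sub) == 0:
            continue
        lr = sub["lr"].to_numpy(dtype=float)
        mbaf = _mirrored(sub["baf"].to_numpy(dtype=float))
        bps = sorted(
            set(segment_vector(lr, alpha, trim, n_perm, min_width, rng))
            | set(segment_vector(mbaf, alpha, trim, n_perm, min_width, rng))
        )
        bounds = [0, *bps, len(sub)]
        segs = []
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            segs.append({
                "chrom": chrom,
                "start": int(sub["start"].iloc[b0]),
                "end": int(sub["end"].iloc[b1 - 1]),
                "n_bins": b1 - b0,
                "lr_mean": float(np.nanmean(lr[b0:b1])),
                "baf_mean": float(np.nanmean(mbaf[b0:b1])),
                "lr_sd": float(np.nanstd(lr[b0:b1], ddof=1)) if b1 - b0 > 1 else 0.0,
                "baf_sd": float(np.nanstd(mbaf[b0:b1], ddof=1)) if b1 - b0 > 1 else 0.0,
            })
            if "arm" in sub.columns:
                segs[-1]["arm"] = sub["arm"].iloc[b0]

        # iterative pruning: merge similar neighbours, shortest first
        def mergeable(a, b):
            return (abs(a["lr_mean"] - b["lr_mean"]) < tol_lr
                    and abs(a["baf_mean"] - b["baf_mean"]) < tol_baf)

        changed = True
        while changed and len(segs) > 1:
            changed = False
            candidates = [
                (min(segs[i]["n_bins"], segs[i + 1]["n_bins"]), i)
                for i in range(len(segs) - 1)
                if mergeable(segs[i], segs[i + 1])
                and segs[i].get("arm") == segs[i + 1].get("arm")
            ]
            if not candidates:
                break
            _, i = min(candidates)
            a, b = segs[i], segs[i + 1]
            na, nb = a["n_bins"], b["n_bins"]
            merged = dict(a)
            merged["end"] = b["end"]
            merged["n_bins"] = na + nb
            merged["lr_mean"] = (a["lr_mean"] * na + b["lr_mean"] * nb) / (na + nb)
            merged["baf_mean"] = (a["baf_mean"] * na + b["baf_mean"] * nb) / (na + nb)
            merged["lr_sd"] = max(a["lr_sd"], b["lr_sd"])
            merged["baf_sd"] = max(a["baf_sd"], b["baf_sd"])
            segs[i:i + 2] = [merged]
            changed = True
        rows.extend(segs)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# purity / ploidy inference


@dataclass
class PloidySolution:
    purity: float
    ploidy: float
    loglik: float
    states: pd.DataFrame
    rank: int = 0
    identifiable: bool = True
    notes: list = field(default_factory=list)


def _state_grid(max_copy: int):
    states = [(c, k) for c in range(max_copy + 1) for k in range(c // 2 + 1)]
    return np.array([s[0] for s in states]), np.array([s[1] for s in states])


def fit_purity_ploidy(
    segments: pd.DataFrame,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    max_copy: int = 8,
    lr_centered: bool = False,
    max_homozygous_len: float = 10e6,
    se_floor: float = 5e-3,
    n_solutions: int = 10,
) -> list:
    """Grid search over purity (and ploidy when LR is mean-centered),
    assigning each segment the (C, K) state maximizing a Gaussian likelihood
    of its (LR mean, mirrored BAF mean); candidates are ranked by total
    length-weighted log-likelihood.

    Solutions implying a large fully homozygous-deleted segment (C = 0
    longer than ``max_homozygous_len``) are rejected. If the likelihood is
    flat across the purity grid (e.g., an all-diploid genome) the returned
    solutions carry ``identifiable=False``.
    """
    if len(segments) < 3:
        raise ValueError("fit_purity_ploidy requires >= 3 segments")
    span = float((segments["end"] - segments["start"]).sum())
    if span < 10e6:
        raise ValueError("segments must span >= 10 Mb")
    if purity_grid is None:
        purity_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 4)
    if ploidy_grid is None:
        ploidy_grid = np.round(np.arange(1.0, 6.0 + 1e-9, 0.05), 4)

    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    wts = lengths / lengths.sum()
    lr_obs = segments["lr_mean"].to_numpy(dtype=float)
    baf_obs = segments["baf_mean"].to_numpy(dtype=float)  # mirrored, >= 0.5
    n_bins = segments.get("n_bins", pd.Series(np.ones(len(segments)))).to_numpy(dtype=float)
    lr_sd = segments.get("lr_sd", pd.Series(np.zeros(len(segments)))).to_numpy(dtype=float)
    baf_sd = segments.get("baf_sd", pd.Series(np.zeros(len(segments)))).to_numpy(dtype=float)
    pooled_lr = max(float(np.nanmedian(lr_sd[lr_sd > 0])) if (lr_sd > 0).any() else 0.0, se_floor)
    pooled_baf = max(float(np.nanmedian(baf_sd[baf_sd > 0])) if (baf_sd > 0).any() else 0.0, se_floor)
    se_lr = np.maximum(pooled_lr / np.sqrt(n_bins), se_floor)
    se_baf = np.maximum(pooled_baf / np.sqrt(n_bins), se_floor)

    C, K = _state_grid(max_copy)

    def evaluate(p: float, shift: float):
        e_lr = expected_lr(C, K, p) - shift                       # (n_states,)
        e_baf = 1.0 - expected_baf(C, K, p)                       # mirrored major allele
        e_baf = np.nan_to_num(e_baf, nan=0.5)                     # C=0 at purity 1
        ll = (
            sps.norm.logpdf(lr_obs[:, None], e_lr[None, :], se_lr[:, None])
            + sps.norm.logpdf(baf_obs[:, None], e_baf[None, :], se_baf[:, None])
        )
        best = np.argmax(ll, axis=1)
        seg_ll = ll[np.arange(len(lr_obs)), best]
        total = float(np.sum(wts * seg_ll))
        c_hat, k_hat = C[best], K[best]
        if np.any((c_hat == 0) & (lengths > max_homozygous_len)):
            total = -np.inf
        return total, c_hat, k_hat

    candidates = []
    if lr_centered:
        for pl in ploidy_grid:
            for p in purity_grid:
                shift = np.log2((p * pl + 2.0 * (1.0 - p)) / 2.0)
                total, c_hat, k_hat = evaluate(float(p), float(shift))
                implied = float(np.sum(wts * c_hat))
                # prefer internally consistent (ploidy ~ implied mean copy)
                total -= 0.01 * (implied - pl) ** 2
                candidates.append((total, float(p), float(pl), c_hat, k_hat))
    else:
        for p in purity_grid:
            total, c_hat, k_hat = evaluate(float(p), 0.0)
            implied = float(np.sum(wts * c_hat))
            candidates.append((total, float(p), implied, c_hat, k_hat))

    # rank by likelihood; break near-ties by parsimony (lower ploidy, then
    # higher purity) since copy-state aliases at half purity / doubled ploidy
    # are exact likelihood ties
    candidates.sort(key=lambda c: (-round(c[0], 6), c[2], -c[1]))
    finite = [c for c in candidates if np.isfinite(c[0])]
    if not finite:
        raise ValueError("no admissible purity/ploidy solution")
    lls = np.array([c[0] for c in finite])
    identifiable = (lls.max() - np.median(lls)) > 1e-6

    solutions = []
    for rank, (total, p, pl, c_hat, k_hat) in enumerate(finite[:n_solutions], start=1):
        states = segments.copy()
        states["C"] = c_hat
        states["K"] = k_hat
        notes = [] if identifiable else ["purity unidentifiable: flat likelihood plateau"]
        solutions.append(PloidySolution(
            purity=p, ploidy=pl, loglik=total, states=states,
            rank=rank, identifiable=identifiable, notes=notes,
        ))
    return solutions


# ---------------------------------------------------------------------------
# arm events and genome instability


def arm_events(
    states: pd.DataFrame,
    gain_threshold: float = 0.5,
    loss_threshold: float = -0.5,
    loh_threshold: float = 0.5,
    loh_requires_loss: bool = False,
) -> pd.DataFrame:
    """Per-arm length-weighted copy score relative to diploid and LOH
    proportion.

    score = sum(len * (C - 2)) / sum(len); gain when score > 0.5, loss when
    score < -0.5. LOH proportion counts K = 0 segments (including
    copy-neutral LOH); LOH is called when the proportion exceeds 0.5 --
    restricted to arms with loss when ``loh_requires_loss``.
    """
    req = {"chrom", "arm", "start", "end", "C", "K"}
    missing = req - set(states.columns)
    if missing:
        raise ValueError(f"states table missing columns: {sorted(missing)}")
    rows = []
    for (chrom, arm), sub in states.groupby(["chrom", "arm"], sort=False):
        length = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        total = length.sum()
        if total <= 0:
            continue
        score = float(np.sum(length * (sub["C"].to_numpy() - 2.0)) / total)
        loh_prop = float(np.sum(length[sub["K"].to_numpy() == 0]) / total)
        call = "gain" if score > gain_threshold else (
            "loss" if score < loss_threshold else "neutral")
        loh_eligible = (call == "loss") if loh_requires_loss else True
        rows.append({
            "chrom": chrom,
            "arm": arm,
            "score": score,
            "call": call,
            "loh_proportion": loh_prop,
            "loh": bool(loh_eligible and loh_prop > loh_threshold),
        })
    return pd.DataFrame(rows)


def genome_instability(
    states: pd.DataFrame,
    genome_length: float | None = None,
    cutoff: float = 0.85,
) -> tuple[float, bool]:
    """Proportion of the genome altered: length fraction of segments whose
    state differs from (C=2, K=1). Unstable when PGA >= ``cutoff``."""
    length = (states["end"] - states["start"]).to_numpy(dtype=float)
    if genome_length is None:
        genome_length = float(length.sum())
    altered = ~((states["C"].to_numpy() == 2) & (states["K"].to_numpy() == 1))
    pga = float(np.sum(length[altered]) / genome_length)
    return pga, pga >= cutoff
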