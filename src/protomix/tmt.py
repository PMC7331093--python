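"""Isobaric reporter-ion quantification: PSM filtering, ratio-to-reference
conversion, IQR-trimmed median summarization, MAD normalization, and
back-conversion to the absolute intensity scale.

The PSM table is a pandas DataFrame with one row per peptide-spectrum match
and reporter channels in ``intensity_<channel>`` columns; the plex design
maps (plex, channel) to sample names and designates exactly one reference
channel per plex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RatioMatrix",
    "filter_psms",
    "psm_ratios",
    "iqr_trim",
    "summarize_level",
    "mad_normalize",
    "reference_intensity",
    "to_abundance",
    "quantify",
]

LEVELS = ("gene", "protein", "peptide", "site")


class SchemaError(ValueError):
    """Raised when the PSM table or plex design violates the contract."""


@dataclass
class RatioMatrix:
    """Entries x samples log2 ratio-to-reference values plus the location/
    scale statistics used by MAD normalization."""

    level: str
    values: pd.DataFrame
    sample_medians: pd.Series | None = None   # M_i
    global_median: float | None = None        # M_0
    sample_mads: pd.Series | None = None      # MAD_i
    global_mad: float | None = None           # MAD_0


def _intensity_cols(psm: pd.DataFrame) -> list:
    cols = [c for c in psm.columns if c.startswith("intensity_")]
    if not cols:
        raise SchemaError("PSM table has no intensity_<channel> columns")
    return cols


def _reference_channels(design: pd.DataFrame) -> pd.Series:
    """plex -> reference channel name; errors unless exactly one per plex."""
    refs = design[design["is_reference"]]
    counts = refs.groupby("plex").size()
    all_plexes = design["plex"].unique()
    bad = [p for p in all_plexes if counts.get(p, 0) != 1]
    if bad:
        raise SchemaError(f"plexes without exactly one reference channel: {bad}")
    return refs.set_index("plex")["channel"]


def _ion_key(psm: pd.DataFrame) -> pd.Series:
    """Peptide-ion identity within a run: sequence + charge (+ site
    configuration when present)."""
    key = psm["peptide"].astype(str)
    if "charge" in psm.columns:
        key = key + "/" + psm["charge"].astype(str)
    if "sites" in psm.columns:
        key = key + "|" + psm["sites"].fillna("").astype(str)
    return key


def _reference_intensity_column(psm: pd.DataFrame, refs: pd.Series) -> pd.Series:
    """Reference-channel reporter intensity of each PSM row."""
    out = pd.Series(np.nan, index=psm.index, dtype=float)
    for plex, ch in refs.items():
        col = f"intensity_{ch}"
        mask = psm["plex"] == plex
        if col in psm.columns:
            out.loc[mask] = psm.loc[mask, col].astype(float)
    return out


def filter_psms(
    psm: pd.DataFrame,
    design: pd.DataFrame,
    phospho_mode: bool = False,
) -> pd.DataFrame:
    """Apply the PSM quality filters in order and resolve redundant PSMs.

    Removes, sequentially: (a) unlabeled PSMs; (b) PSMs with zero/missing
    reference-channel intensity; (c) precursor purity < 0.5; (d) summed
    reporter intensity below the 5th percentile of the plex's PSM file
    (2.5th in ``phospho_mode``); (e) non-phosphorylated peptides when
    ``phospho_mode``; contaminants. Among redundant PSMs of one peptide ion
    in one plex, keeps the single PSM with the highest summed reporter
    intensity (ties: first by spectrum id).

    The per-plex intensity floor is stamped on the output in an
    ``intensity_floor`` column and reused on re-application, making the
    filter idempotent.
    """
    refs = _reference_channels(design)
    icols = _intensity_cols(psm)
    out = psm.copy()

    if "labeled" in out.columns:
        out = out[out["labeled"].astype(bool)]

    ref_int = _reference_intensity_column(out, refs)
    out = out[ref_int.notna() & (ref_int > 0)]

    if "precursor_purity" in out.columns:
        out = out[out["precursor_purity"] >= 0.5]

    summed = out[icols].sum(axis=1)
    pct = 2.5 if phospho_mode else 5.0
    if "intensity_floor" in out.columns:
        floors = out["intensity_floor"]
    else:
        floors = summed.groupby(out["plex"]).transform(
            lambda v: np.percentile(v, pct)
        )
    out = out[summed >= floors]
    out = out.assign(intensity_floor=floors.loc[out.index])

    if phospho_mode:
        if "sites" not in out.columns:
            raise SchemaError("phospho_mode requires a 'sites' column")
        has_site = out["sites"].notna() & (out["sites"].astype(str) != "")
        out = out[has_site]

    if "contaminant" in out.columns:
        out = out[~out["contaminant"].astype(bool)]

    # redundancy: one PSM per peptide ion per plex, highest summed intensity
    summed = out[icols].sum(axis=1)
    key = _ion_key(out)
    best = (
        pd.DataFrame({"plex": out["plex"], "ion": key, "summed": summed,
                      "spectrum": out.get("spectrum", out.index)})
        .sort_values(["plex", "ion", "summed", "spectrum"],
                     ascending=[True, True, False, True], kind="mergesort")
        .drop_duplicates(["plex", "ion"], keep="first")
    )
    return out.loc[best.index.sort_values()]


def psm_ratios(psm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-PSM log2 ratios to the plex reference channel.

    Zero intensity in a non-reference channel yields a missing ratio, not
    -inf. Returns one row per (PSM, sample) with metadata columns carried
    through.
    """
    refs = _reference_channels(design)
    meta_cols = [c for c in psm.columns if not c.startswith("intensity_")]
    frames = []
    for plex, sub in psm.groupby("plex", sort=True):
        ref_ch = refs[plex]
        ref = sub[f"intensity_{ref_ch}"].astype(float)
        members = design[(design["plex"] == plex) & (~design["is_reference"])]
        for _, m in members.iterrows():
            col = f"intensity_{m['channel']}"
            if col not in sub.columns:
                raise SchemaError(f"missing column {col} for plex {plex}")
            inten = sub[col].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.log2(inten) - np.log2(ref)
            ratio = ratio.where((inten > 0) & (ref > 0))
            block = sub[meta_cols].copy()
            block["sample"] = m["sample"]
            block["ratio"] = ratio
            frames.append(block)
    return pd.concat(frames, ignore_index=True)


def iqr_trim(values) -> np.ndarray:
    """Drop values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation between order statistics. NaNs are
    dropped first; an empty input is an error.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("iqr_trim requires at least one finite value")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def _entry_key(ratios: pd.DataFrame, level: str) -> pd.Series:
    if level == "gene":
        return ratios["gene"].astype(str)
    if level == "protein":
        return ratios["protein"].astype(str)
    if level == "peptide":
        return ratios["peptide"].astype(str)
    if level == "site":
        if "sites" not in ratios.columns:
            raise SchemaError("site-level summarization requires a 'sites' column")
        return ratios["peptide"].astype(str) + "|" + ratios["sites"].fillna("").astype(str)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def summarize_level(ratios: pd.DataFrame, level: str) -> RatioMatrix:
    """Entries x samples ratio matrix: per cell, IQR-trim the PSM ratios and
    take the median of the survivors."""
    key = _entry_key(ratios, level)
    df = ratios.assign(_entry=key)

    def cell(v):
        v = v.dropna().to_numpy()
        if v.size == 0:
            return np.nan
        return float(np.median(iqr_trim(v)))

    mat = (
        df.groupby(["_entry", "sample"], sort=True)["ratio"]
        .apply(cell)
        .unstack("sample")
    )
    mat.index.name = level
    return RatioMatrix(level=level, values=mat)


def mad_normalize(matrix: RatioMatrix) -> RatioMatrix:
    """Median-center each sample and rescale its spread to the global MAD:

    R_centered = R - M_i;  R_norm = (R_centered / MAD_i) * MAD_0 + M_0

    with M_i the per-sample median, M_0 the median of the M_i, MAD_i the
    per-sample median absolute deviation of centered values, and MAD_0 the
    median of the MAD_i. Missing values pass through untouched.
    """
    R = matrix.values
    M_i = R.median(axis=0, skipna=True)
    M_0 = float(M_i.median())
    centered = R.sub(M_i, axis=1)
    MAD_i = centered.abs().median(axis=0, skipna=True)
    zero = MAD_i[MAD_i == 0]
    if len(zero):
        raise ValueError(f"zero MAD for sample(s): {list(zero.index)}")
    MAD_0 = float(MAD_i.median())
    normalized = centered.div(MAD_i, axis=1) * MAD_0 + M_0
    return RatioMatrix(
        level=matrix.level,
        values=normalized,
        sample_medians=M_i,
        global_median=M_0,
        sample_mads=MAD_i,
        global_mad=MAD_0,
    )


def reference_intensity(
    psm: pd.DataFrame,
    design: pd.DataFrame,
    level: str,
    impute_entries=None,
) -> pd.Series:
    """Per-entry reference intensity REF_i.

    Per plex, REF_ik is the weighted sum of the MS1 intensities of the top
    three most intense peptide ions of the entry, weighting each by the
    reference channel's share of the summed reporter intensity; REF_i is
    the arithmetic mean of REF_ik over plexes with data. Entries listed in
    ``impute_entries`` but absent from the table receive the global minimum
    REF.
    """
    refs = _reference_channels(design)
    icols = _intensity_cols(psm)
    if "ms1_intensity" not in psm.columns:
        raise SchemaError("reference_intensity requires an 'ms1_intensity' column")
    entry = _entry_key(psm, level)
    ref_int = _reference_intensity_column(psm, refs).to_numpy(dtype=float)
    summed = psm[icols].sum(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        weight = np.where(summed > 0, ref_int / summed, 0.0)
    work = pd.DataFrame({
        "entry": entry.to_numpy(),
        "plex": psm["plex"].to_numpy(),
        "ion": _ion_key(psm).to_numpy(),
        "ms1": psm["ms1_intensity"].to_numpy(dtype=float),
        "w": weight,
    })
    # one record per peptide ion per plex (table is already deduplicated by
    # filter_psms; guard anyway by keeping the most intense)
    work = (
        work.sort_values(["entry", "plex", "ion", "ms1"], ascending=[True, True, True, False])
        .drop_duplicates(["entry", "plex", "ion"], keep="first")
    )

    def ref_ik(g: pd.DataFrame) -> float:
        top = g.nlargest(3, "ms1")
        return float((top["ms1"] * top["w"]).sum())

    per_plex = work.groupby(["entry", "plex"]).apply(ref_ik, include_groups=False)
    ref_i = per_plex.groupby(level=0).mean()
    ref_i.index.name = level
    if len(ref_i) == 0:
        raise ValueError("no entries with qualifying PSMs")
    if impute_entries is not None:
        global_min = float(ref_i.min())
        ref_i = ref_i.reindex(pd.Index(impute_entries, name=level))
        ref_i = ref_i.fillna(global_min)
    return ref_i


def to_abundance(matrix: RatioMatrix, ref: pd.Series) -> pd.DataFrame:
    """Shift normalized ratios onto the absolute log2 intensity scale:
    A_ij = R_norm_ij + log2(REF_i)."""
    common = matrix.values.index.intersection(ref.index)
    if len(common) < len(matrix.values.index):
        missing = matrix.values.index.difference(ref.index)
        raise ValueError(f"reference intensities missing for entries: {list(missing)[:5]}")
    r = ref.loc[matrix.values.index]
    if (r <= 0).any():
        bad = list(r[r <= 0].index[:5])
        raise ValueError(f"non-positive reference intensity for entries: {bad}")
    return matrix.values.add(np.log2(r), axis=0)


def quantify(
    psm: pd.DataFrame,
    design: pd.DataFrame,
    level: str = "gene",
    phospho_mode: bool = False,
) -> dict:
    """End-to-end quantification: filter -> ratios -> summarize -> MAD
    normalize -> abundance. Returns the intermediate products keyed by
    stage name."""
    filtered = filter_psms(psm, design, phospho_mode=phospho_mode)
    ratios = psm_ratios(filtered, design)
    ratio_matrix = summarize_level(ratios, level)
    normalized = mad_normalize(ratio_matrix)
    ref = reference_intensity(
        filtered, design, level, impute_entries=normalized.values.index
    )
    abundance = to_abundance(normalized, ref)
    return {
        "filtered": filtered,
        "ratios": ratio_matrix,
        "normalized": normalized,
        "abundance": abundance,
        "reference_intensity": ref,
    }
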