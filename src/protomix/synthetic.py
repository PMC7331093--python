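"""Synthetic multi-omic tumor/NAT cohort generator with recorded ground truth.

Every downstream stage of the pipeline has a parameter-recovery test driven
by this module: it emits PSM-level proteomics tables, log2 abundance
matrices (mRNA / protein / phosphosite / methylation beta), binned LR/BAF
copy-number tracks with known integer states, cell-type score matrices with
planted archetype groups, and clinical covariates -- all deterministic for a
fixed seed.

The expression model mixes a pure-tumor profile y and a stroma/immune
profile z by per-sample purity pi:  X_ij = pi_i * y_ij + (1 - pi_i) * z_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_expression",
    "generate_psm_table",
    "generate_segments",
    "generate_cell_scores",
    "generate_methylation",
    "generate_clinical",
    "expected_lr",
    "expected_baf",
]


class ConfigError(ValueError):
    """Raised for an invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Knobs for the synthetic cohort.

    ``plex_size`` counts channels per plex; one channel is reserved for the
    pooled reference, so each plex carries ``plex_size - 1`` samples.
    ``purity_range`` bounds the uniform tumor-purity distribution and must
    sit strictly inside (0, 1).
    """

    n_tumor: int = 20
    n_nat: int = 20
    n_genes: int = 200
    peptides_per_gene: tuple[int, int] = (1, 4)
    psms_per_peptide: tuple[int, int] = (1, 3)
    plex_size: int = 10
    purity_range: tuple[float, float] = (0.4, 0.9)
    nat_purity_range: tuple[float, float] = (0.05, 0.2)
    # log2 effects added to the pure-tumor profile of named genes
    tumor_effects: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=lambda: {
        "expression": 0.3,
        "reporter": 0.05,
        "lr": 0.08,
        "baf": 0.02,
        "cell_score": 1.0,
    })
    # fraction of PSMs planted to fail each quality rule
    flag_rates: dict = field(default_factory=lambda: {
        "unlabeled": 0.02,
        "low_purity": 0.03,
        "contaminant": 0.02,
        "missing_reference": 0.02,
    })
    # copy-number track geometry
    n_chroms: int = 4
    arm_bins: int = 300
    bin_size: int = 10_000
    # cell-score space
    n_cell_types: int = 30
    n_subtypes: int = 4
    subtype_separation: float = 4.0
    # phospho
    sites_per_gene: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_nat", "n_genes", "plex_size", "n_chroms", "arm_bins"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.plex_size < 2:
            raise ConfigError("plex_size must leave room for a reference channel")
        for rng_name in ("purity_range", "nat_purity_range"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 < lo <= hi < 1.0):
                raise ConfigError(f"{rng_name} must lie strictly inside (0, 1)")
        for pair in ("peptides_per_gene", "psms_per_peptide", "sites_per_gene"):
            lo, hi = getattr(self, pair)
            if lo < 1 or hi < lo:
                raise ConfigError(f"{pair} must be a positive (lo, hi) range")


@dataclass
class GroundTruth:
    """Generating parameters recorded alongside the cohort."""

    mu_tumor: pd.Series          # pure-tumor log2 profile (tumor tissue)
    mu_nat: pd.Series            # pure-tissue log2 profile (NAT)
    mu_stroma: pd.Series         # stroma/immune log2 profile (shared)
    purity: pd.Series            # per sample
    tumor_effects: dict          # gene -> planted log2 effect on pure tumor
    planted_cis: list = field(default_factory=list)    # (gene, variation, sign)
    planted_trans: list = field(default_factory=list)  # (event, [genes], sign)
    planted_subtype: pd.Series | None = None
    copy_states: dict = field(default_factory=dict)    # sample -> segment frame
    cimp_positive: list = field(default_factory=list)
    kinase_events: list = field(default_factory=list)  # (site, log2 fc)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    truth: GroundTruth
    psm: pd.DataFrame
    design: pd.DataFrame
    matrices: dict                 # layer name -> feature x sample frame
    tracks: dict                   # sample -> binned LR/BAF frame
    cell_scores: pd.DataFrame
    clinical: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write every artifact as TSV under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.psm.to_csv(outdir / "psm.tsv", sep="\t", index=False)
        self.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        for name, mat in self.matrices.items():
            mat.to_csv(outdir / f"{name}.tsv", sep="\t")
        for sample, track in self.tracks.items():
            track.to_csv(outdir / f"track_{sample}.tsv", sep="\t", index=False)
        self.cell_scores.to_csv(outdir / "cell_scores.tsv", sep="\t")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t")
        self.truth.purity.to_frame("purity").to_csv(outdir / "truth_purity.tsv", sep="\t")
        pd.concat(
            {s: df for s, df in self.truth.copy_states.items()}, names=["sample"]
        ).reset_index(level=0).to_csv(outdir / "truth_copy_states.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression layers


def _sample_names(config: CohortConfig) -> tuple[list, list]:
    tumors = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    nats = [f"N{i + 1:03d}" for i in range(config.n_nat)]
    return tumors, nats


def generate_expression(config: CohortConfig, rng: np.random.Generator):
    """Purity-mixed log2 expression for tumor and NAT samples.

    Returns ``(matrix, truth)`` where the matrix holds genes x samples and
    the truth records pure profiles, purity and planted effects.
    """
    config.validate()
    genes = pd.Index([f"G{i + 1:04d}" for i in range(config.n_genes)], name="gene")
    tumors, nats = _sample_names(config)

    mu_tumor = pd.Series(rng.normal(0.0, 1.0, config.n_genes), index=genes)
    mu_nat = pd.Series(rng.normal(0.0, 1.0, config.n_genes), index=genes)
    mu_stroma = pd.Series(rng.normal(0.0, 1.0, config.n_genes), index=genes)
    for gene, eff in config.tumor_effects.items():
        if gene not in genes:
            raise ConfigError(f"planted effect names unknown gene {gene!r}")
        mu_tumor.loc[gene] += eff

    pi_t = rng.uniform(*config.purity_range, config.n_tumor)
    pi_n = rng.uniform(*config.nat_purity_range, config.n_nat)
    purity = pd.Series(
        np.concatenate([pi_t, pi_n]), index=tumors + nats, name="purity"
    )

    sd = config.noise_sd.get("expression", 0.0)
    cols = {}
    for i, s in enumerate(tumors):
        y = mu_tumor.to_numpy() + rng.normal(0, sd, config.n_genes)
        z = mu_stroma.to_numpy() + rng.normal(0, sd, config.n_genes)
        cols[s] = pi_t[i] * y + (1 - pi_t[i]) * z
    for i, s in enumerate(nats):
        y = mu_nat.to_numpy() + rng.normal(0, sd, config.n_genes)
        z = mu_stroma.to_numpy() + rng.normal(0, sd, config.n_genes)
        cols[s] = pi_n[i] * y + (1 - pi_n[i]) * z
    matrix = pd.DataFrame(cols, index=genes)

    truth = GroundTruth(
        mu_tumor=mu_tumor,
        mu_nat=mu_nat,
        mu_stroma=mu_stroma,
        purity=purity,
        tumor_effects=dict(config.tumor_effects),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# PSM-level proteomics


def _plex_design(config: CohortConfig, samples: list) -> pd.DataFrame:
    """Assign every sample to exactly one (plex, channel); the last channel
    of each plex carries the pooled reference."""
    per_plex = config.plex_size - 1
    rows = []
    for i, sample in enumerate(samples):
        plex = i // per_plex + 1
        channel = i % per_plex + 1
        rows.append((f"plex{plex:02d}", f"ch{channel:02d}", sample, False))
    n_plex = (len(samples) + per_plex - 1) // per_plex
    ref_ch = f"ch{config.plex_size:02d}"
    for p in range(1, n_plex + 1):
        rows.append((f"plex{p:02d}", ref_ch, f"REF_plex{p:02d}", True))
    return pd.DataFrame(rows, columns=["plex", "channel", "sample", "is_reference"])


def generate_psm_table(
    gene_log2: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
):
    """PSM table with reporter intensities derived from gene-level log2
    abundances, plus the plex design.

    Reporter content per channel is proportional to 2**abundance of the
    channel's sample, with multiplicative lognormal noise; the pooled
    reference channel carries the cohort mean on the linear scale. A
    configured fraction of PSMs is planted to fail each quality rule.
    """
    config.validate()
    samples = list(gene_log2.columns)
    design = _plex_design(config, samples)
    linear = np.power(2.0, gene_log2)
    ref_content = linear.mean(axis=1)  # pooled reference: all samples

    rep_sd = config.noise_sd.get("reporter", 0.0)
    rows = []
    spectrum = 0
    plex_groups = design[~design.is_reference].groupby("plex", sort=True)
    for gi, gene in enumerate(gene_log2.index):
        n_pep = rng.integers(config.peptides_per_gene[0], config.peptides_per_gene[1] + 1)
        for pi in range(n_pep):
            peptide = f"{gene}_PEP{pi + 1}"
            ms1 = float(rng.lognormal(mean=15.0, sigma=1.0))
            for plex, members in plex_groups:
                n_psm = rng.integers(
                    config.psms_per_peptide[0], config.psms_per_peptide[1] + 1
                )
                base = float(rng.lognormal(mean=8.0, sigma=0.5))
                for k in range(n_psm):
                    spectrum += 1
                    rec = {
                        "plex": plex,
                        "spectrum": f"sp{spectrum:07d}",
                        "peptide": peptide,
                        "charge": 2,
                        "gene": gene,
                        "protein": f"{gene}_PROT",
                        "unique_razor": True,
                        "contaminant": False,
                        "labeled": True,
                        "precursor_purity": float(rng.uniform(0.5, 1.0)),
                        "ms1_intensity": ms1 * float(rng.lognormal(0, 0.1)),
                    }
                    # attenuate later PSMs of the same ion so redundancy
                    # resolution has a deterministic winner
                    scale = base * (1.0 - 0.1 * k)
                    for _, row in members.iterrows():
                        noise = rng.lognormal(0.0, rep_sd) if rep_sd > 0 else 1.0
                        rec[f"intensity_{row.channel}"] = (
                            scale * linear.at[gene, row["sample"]] * noise
                        )
                    ref_noise = rng.lognormal(0.0, rep_sd) if rep_sd > 0 else 1.0
                    ref_ch = f"ch{config.plex_size:02d}"
                    rec[f"intensity_{ref_ch}"] = scale * ref_content.loc[gene] * ref_noise
                    rows.append(rec)
    psm = pd.DataFrame(rows)

    # plant quality failures
    n = len(psm)
    for rule, rate in config.flag_rates.items():
        if rate <= 0:
            continue
        idx = rng.random(n) < rate
        if rule == "unlabeled":
            psm.loc[idx, "labeled"] = False
        elif rule == "low_purity":
            psm.loc[idx, "precursor_purity"] = rng.uniform(0.0, 0.499, idx.sum())
        elif rule == "contaminant":
            psm.loc[idx, "contaminant"] = True
        elif rule == "missing_reference":
            ref_ch = f"ch{config.plex_size:02d}"
            psm.loc[idx, f"intensity_{ref_ch}"] = 0.0
    return psm, design


# ---------------------------------------------------------------------------
# copy number


def expected_lr(C, K, purity):  # noqa: ARG001 - K unused, kept for symmetry
    """Expected log coverage-ratio of a segment in state (C, K) at the given
    purity, relative to a diploid normal."""
    C = np.asarray(C, float)
    p = np.asarray(purity, float)
    with np.errstate(divide="ignore"):
        return np.log2((p * C + 2.0 * (1.0 - p)) / 2.0)


def expected_baf(C, K, purity):
    """Expected B-allele frequency (minor allele) of state (C, K)."""
    C = np.asarray(C, float)
    K = np.asarray(K, float)
    p = np.asarray(purity, float)
    denom = p * C + 2.0 * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (p * K + (1.0 - p)) / denom


_STATE_POOL = [(2, 1), (1, 0), (3, 1), (2, 0), (4, 2), (4, 1), (3, 0)]
_STATE_WEIGHTS = [0.45, 0.13, 0.13, 0.09, 0.08, 0.06, 0.06]


def make_copy_states(
    config: CohortConfig,
    rng: np.random.Generator,
    max_segments_per_arm: int = 2,
    min_seg_bins: int = 30,
) -> pd.DataFrame:
    """Random integer copy states partitioning each chromosome arm.

    Segments are at least ``min_seg_bins`` bins long so planted breakpoints
    remain detectable at finite SNR.
    """
    rows = []
    arm_len = config.arm_bins * config.bin_size
    min_seg_bins = min(min_seg_bins, max(config.arm_bins // 3, 1))
    for c in range(1, config.n_chroms + 1):
        for arm_i, arm in enumerate(("p", "q")):
            start0 = arm_i * arm_len
            n_seg = int(rng.integers(1, max_segments_per_arm + 1))
            cuts = np.sort(rng.choice(
                np.arange(min_seg_bins, config.arm_bins - min_seg_bins + 1),
                n_seg - 1, replace=False)) if n_seg > 1 else np.array([], int)
            bounds = np.concatenate([[0], cuts, [config.arm_bins]])
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                si = rng.choice(len(_STATE_POOL), p=_STATE_WEIGHTS)
                C, K = _STATE_POOL[si]
                rows.append((
                    f"chr{c}", start0 + b0 * config.bin_size,
                    start0 + b1 * config.bin_size, arm, C, K,
                ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "arm", "C", "K"])


def generate_segments(
    config: CohortConfig,
    copy_states: pd.DataFrame,
    purity: float,
    rng: np.random.Generator,
    gc_slope: float = 0.0,
) -> pd.DataFrame:
    """Binned LR/BAF track realizing the given copy states at a purity.

    The expected LR of a bin in state (C, K) is log2((p*C + 2(1-p)) / 2) and
    the expected BAF is (p*K + (1-p)) / (p*C + 2(1-p)); BAF is emitted with
    a random allele orientation. ``gc_slope`` plants a linear GC bias on LR,
    centered at GC = 0.5.
    """
    lr_sd = config.noise_sd.get("lr", 0.0)
    baf_sd = config.noise_sd.get("baf", 0.0)
    frames = []
    for seg in copy_states.itertuples():
        n_bins = (seg.end - seg.start) // config.bin_size
        starts = seg.start + np.arange(n_bins) * config.bin_size
        gc = np.clip(rng.uniform(0.25, 0.75, n_bins), 0.0, 1.0)
        lr = expected_lr(seg.C, seg.K, purity) + gc_slope * (gc - 0.5)
        if lr_sd > 0:
            lr = lr + rng.normal(0, lr_sd, n_bins)
        else:
            lr = np.full(n_bins, lr)
        b = float(expected_baf(seg.C, seg.K, purity))
        baf = np.where(rng.random(n_bins) < 0.5, b, 1.0 - b)
        if baf_sd > 0:
            baf = np.clip(baf + rng.normal(0, baf_sd, n_bins), 0.0, 1.0)
        frames.append(pd.DataFrame({
            "chrom": seg.chrom,
            "start": starts,
            "end": starts + config.bin_size,
            "arm": seg.arm,
            "lr": lr,
            "baf": baf,
            "gc": gc,
            "mappable": True,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# other layers


def generate_cell_scores(config: CohortConfig, samples: list, rng: np.random.Generator):
    """Cell-type score matrix with planted archetype groups.

    Returns ``(scores, labels)``; each archetype raises a disjoint block of
    cell types by ``subtype_separation``.
    """
    types = pd.Index([f"cell{t + 1:02d}" for t in range(config.n_cell_types)], name="cell_type")
    k = config.n_subtypes
    labels = pd.Series(
        [f"grp{(i % k) + 1}" for i in range(len(samples))], index=samples, name="subtype"
    )
    block = config.n_cell_types // k
    archetypes = {}
    for gi in range(k):
        v = np.zeros(config.n_cell_types)
        v[gi * block:(gi + 1) * block] = config.subtype_separation
        archetypes[f"grp{gi + 1}"] = v
    sd = config.noise_sd.get("cell_score", 1.0)
    data = {
        s: archetypes[labels[s]] + rng.normal(0, sd, config.n_cell_types)
        for s in samples
    }
    return pd.DataFrame(data, index=types), labels


def generate_methylation(
    config: CohortConfig,
    samples: list,
    rng: np.random.Generator,
    n_markers: int = 40,
    cimp_fraction: float = 0.3,
):
    """Beta-value matrix over marker probes with a planted hypermethylated
    (CIMP+) sample block."""
    probes = pd.Index([f"cg{i + 1:05d}" for i in range(n_markers)], name="probe")
    n_pos = max(1, int(round(cimp_fraction * len(samples))))
    positive = list(samples[:n_pos])
    cols = {}
    for s in samples:
        center = 0.7 if s in positive else 0.2
        cols[s] = np.clip(rng.normal(center, 0.05, n_markers), 0.0, 1.0)
    return pd.DataFrame(cols, index=probes), positive


def generate_clinical(config: CohortConfig, samples: list, rng: np.random.Generator):
    """Independent clinical covariates (age, gender, ischemic time, grade)."""
    n = len(samples)
    return pd.DataFrame(
        {
            "age": rng.normal(60, 10, n).round(1),
            "gender": rng.choice(["F", "M"], n),
            "ischemic_time": rng.uniform(5, 60, n).round(1),
            "grade": rng.integers(1, 5, n),
            "stage": rng.integers(1, 5, n),
        },
        index=pd.Index(samples, name="sample"),
    )


# ---------------------------------------------------------------------------
# orchestration


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    expr, truth = generate_expression(config, rng)
    tumors, nats = _sample_names(config)

    # mRNA correlated with protein; protein is the mixture matrix itself
    mrna = expr + rng.normal(0, config.noise_sd.get("expression", 0.3), expr.shape)
    psm, design = generate_psm_table(expr, config, rng)

    # phosphosite layer: sites inherit their gene's abundance plus site noise
    site_rows, site_index = [], []
    for gene in expr.index:
        n_sites = rng.integers(config.sites_per_gene[0], config.sites_per_gene[1] + 1)
        for s in range(n_sites):
            site_index.append(f"{gene}_S{s + 1}")
            site_rows.append(expr.loc[gene].to_numpy() + rng.normal(0, 0.2, expr.shape[1]))
    sites = pd.DataFrame(site_rows, index=pd.Index(site_index, name="site"),
                         columns=expr.columns)

    beta, cimp_pos = generate_methylation(config, tumors, rng)
    truth.cimp_positive = cimp_pos

    # copy number: per-tumor states and tracks
    tracks = {}
    for s in tumors:
        states = make_copy_states(config, rng)
        truth.copy_states[s] = states
        tracks[s] = generate_segments(config, states, float(truth.purity[s]), rng)

    cell_scores, subtype = generate_cell_scores(config, tumors, rng)
    truth.planted_subtype = subtype
    clinical = generate_clinical(config, tumors + nats, rng)

    return SyntheticCohort(
        config=config,
        truth=truth,
        psm=psm,
        design=design,
        matrices={"protein": expr, "mrna": mrna, "phosphosite": sites, "beta": beta},
        tracks=tracks,
        cell_scores=cell_scores,
        clinical=clinical,
    )
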