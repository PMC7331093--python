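# protomix

A tested, reusable pipeline for proteogenomic tumor/normal cohort analysis:

- **`protomix.tmt`** — isobaric (TMT-style) reporter-ion quantification:
  PSM quality filtering, log2 ratio-to-reference conversion, IQR-trimmed
  median summarization at gene/protein/peptide/site level, MAD
  normalization, and back-conversion to absolute intensities via top-3
  weighted MS1 reference intensities.
- **`protomix.cnv`** — copy-number analysis from binned LR/BAF tracks:
  LOESS GC correction, joint CBS-style segmentation of LR and mirrored
  BAF, purity/ploidy grid search with integer (C, K) state assignment,
  arm-level gain/loss/LOH calls, and proportion-genome-altered (PGA)
  genome-instability classification.
- **`protomix.differential`** — tumor-vs-NAT differential expression:
  Wilcoxon rank-sum testing with fold-change/FDR thresholds, a
  purity-aware two-component Gaussian mixture (pure-tissue vs
  stroma/immune) with permutation-FDR calls, and anatomic-region
  allocation of NAT samples.
- **`protomix.association`** — cis/trans association of DNA features with
  molecular traits under covariate adjustment, permutation empirical FDR
  (eFDR) threshold selection, directional biological filters, delta-R²
  decomposition, signed rank-sum pathway scores, and multivariate
  clinical regression.
- **`protomix.crossomics`** — mRNA–protein Spearman correlation (gene-wise
  and sample-wise), covariate models on sample-wise correlation,
  rank-based set enrichment, and cross-omic sample-alignment QC that
  detects swapped samples.
- **`protomix.subtypes`** — consensus clustering (subsampled PAM or
  hierarchical base), methylation-marker (CIMP) classification, and
  chi-square subtype/feature association.
- **`protomix.immune`** — immune subtype discovery on cell-type score
  matrices, group indicator-regression differentials, combined-z
  signature scores, one-vs-rest marker selection, and a two-score
  Spearman transfer classifier for external cohorts.
- **`protomix.phospho`** — kinase–substrate fold-change ranking across
  tumor/NAT pairs, grade comparisons, and module-correlation tests.
- **`protomix.synthetic`** — a synthetic-cohort generator with recorded
  ground truth (PSM tables, multi-omic matrices, copy-number tracks, cell
  scores, clinical covariates) so every stage has a parameter-recovery
  test without external data.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exactness of the
quantification engine on zero-noise data, brute-force filter oracles,
purity-model recovery and FDR control, eFDR calibration and power,
copy-number recovery, clustering/transfer-classifier accuracy, statistical
oracles, and alignment-QC sensitivity).

## CLI

```bash
protomix simulate --out cohort/ --seed 1            # synthetic cohort + truth
protomix quant --psm cohort/psm.tsv --design cohort/design.tsv \
    --level gene --out quant/
protomix cnv segment --track cohort/track_T001.tsv --out segs.tsv
protomix cnv fit --segments segs.tsv --out states.tsv
protomix cnv arms --states states.tsv --out arms.tsv
protomix cnv pga --states states.tsv
protomix diff bulk --tumor t.tsv --nat n.tsv --out diff.tsv
protomix diff deconv --matrix m.tsv --purity p.tsv --tissue t.tsv --out out.tsv
protomix assoc trans --feature f.tsv --traits traits.tsv --out assoc.tsv
protomix xomics corr --mrna mrna.tsv --protein prot.tsv --out corr/
protomix xomics align --a mrna.tsv --b prot.tsv --out align.tsv
protomix subtype consensus --matrix scores.tsv --k 4 --out labels.tsv
protomix subtype cimp --beta beta.tsv --out cimp.tsv
protomix immune group --scores scores.tsv --k 6 --out groups.tsv
protomix phospho rank --sites sites.tsv --pairs pairs.tsv \
    --annotation ksa.tsv --out ranks.tsv
```

All commands exchange plain TSV tables (features as rows, samples as
columns for matrices).

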