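# concordkit

Cross-platform concordance analysis of gene-expression measurements: how well
do single-color microarray expression values track true RNA abundance, where
do they compress, and how noisy are they in different tissues? The package
compares microarray values against count-based nCounter measurements of the
same samples — treating normalized molecule counts as the reference — and
ships a paired-platform simulator so the whole analysis runs, and is tested,
against known truth.

It is aimed at people who interpret microarray log-fold-changes: the analysis
quantifies expression-dependent accuracy bias and tissue-specific precision,
the two effects that most distort that interpretation.

## What it computes

For each cell-type arm, processed independently end to end:

- **nCounter processing** — each sample is scaled so its geometric mean of
  positive-control counts equals the common target (factors flagged outside
  0.3–3); the expression threshold is the median over samples of the maximum
  negative-control count; genes are called expressed when their median scaled
  count exceeds it; counts become log2(count + 1) and are normalized to
  control genes.
- **Microarray preprocessing** — quantile normalization, optional
  median-polish probeset summarization, and parametric empirical-Bayes
  batch correction (ComBat-style location/scale shrinkage) preserving
  diagnosis, sex and age; PCA scores for batch inspection.
- **Control-gene selection** — candidates with mean expression in
  [8, 12] log2 units from the lowest-variance 2% (variance computed within
  batches, averaged across them), plus the binned mean–variance diagnostic.
- **Concordance** — per gene, the Pearson correlation r between platforms
  and the *signal detection slope*: the OLS slope of microarray values on
  control-gene-normalized log counts (slope 1 = accurate, < 1 = compression),
  examined for genes with r > 0.5.
- **Precision** — the SD of all pairwise between-sample log-ratios
  (equal to √2 × sample SD) for nCounter-unexpressed and nCounter-invariant
  genes, compared across cell types with Mann-Whitney tests.

See `docs/methods.md` for the models, conventions and the simulator's
generative assumptions.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
dataset (three leukocyte arms — CD4, CD14, CD16 — 200-gene panel, 42 samples
each; the CD16 arm is single-batch and skips batch correction):

```
python analysis/01_simulate_dataset.py
python analysis/02_process_ncounter.py
python analysis/03_preprocess_microarray.py
python analysis/04_select_control_genes.py
python analysis/05_cross_platform_concordance.py
python analysis/06_recovery_report.py
```

Output of the last two steps (seed 1):

```
CD4: controls ['G046', 'G195']; 155/160 expressed genes pass r > 0.5;
     median slope 0.441; median unexpressed-gene SD 0.216
  noise CD14 vs CD4: U = 1600, p = 1.44e-14
  noise CD16 vs CD4: U = 1600, p = 1.44e-14

generative mid-range slope beta_mid = 0.5
recovered pooled median: 0.478 (abs error 0.022)
above-knee pooled median: 0.358 (saturation)
           call_sensitivity  call_specificity  sd_ratio  control_hit_rate
CD14                    1.0               1.0     0.977               1.0
CD16                    1.0               1.0     0.977               1.0
CD4                     1.0               1.0     1.016               1.0
```

Reading this: the pipeline recovers the simulator's mid-range compression
slope of 0.5 to within 0.022; genes above the saturation knee show clearly
dampened slopes (0.358); negative-control thresholding separates expressed
from unexpressed genes perfectly at these conditions; the unexpressed-gene
noise metric matches its closed-form prediction √2·σ within a few percent per
arm; and the quiet CD4 arm is detected as significantly less noisy than the
CD14/CD16 arms — while CD14 vs CD16, which share a noise level, shows no
difference (p = 0.70).

The same stages are available as a CLI
(`concordkit simulate | nc-normalize | array-preprocess | select-controls |
concordance | report`); matrices travel as TSV (features × samples), counts
as one simplified RCC CSV per sample, annotation as CSV.

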