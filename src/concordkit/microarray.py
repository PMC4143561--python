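"""Microarray-side preprocessing.

Re-implementations of the standard single-color preprocessing stack:

* quantile normalization (the RMA normalization step) — every sample's value
  distribution is forced onto the across-sample mean distribution; tied
  values within a sample receive the mean of the quantile values they span;
* median-polish probeset summarization (the RMA summarization step) — a
  two-way additive model value = overall + probe + sample fit by alternating
  median sweeps, rows first; the per-sample summary is overall + sample
  effect;
* parametric empirical-Bayes batch correction in the ComBat style — per-gene,
  per-batch location (normal prior) and scale (inverse-gamma prior) estimates
  are shrunk toward batch-level priors and removed while specified biological
  covariates are preserved;
* PCA sample scores for batch-effect visualization.

RMA's optical background correction is deliberately omitted: the synthetic
probe data this package analyses carries no additive optical background, so
users comparing against oligo's full RMA should expect that difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DataValidationError,
    ExpressionMatrix,
    PipelineError,
    SampleAnnotation,
)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the across-column mean of sorted values.

    Ties within a column receive the mean of the reference quantile values
    their ranks span, which keeps the transform idempotent on tie-free data
    and rank-faithful otherwise. Requires at least two samples.
    """
    x = em.values.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        raise PipelineError("quantile normalization requires >= 2 samples")
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        col = np.empty(n)
        col[order[:, j]] = reference
        uniq, inv, cnt = np.unique(x[:, j], return_inverse=True, return_counts=True)
        if (cnt > 1).any():
            sums = np.bincount(inv, weights=col)
            col = sums[inv] / cnt[inv]
        out[:, j] = col
    return ExpressionMatrix(
        pd.DataFrame(out, index=em.values.index, columns=em.values.columns),
        scale=em.scale,
    )


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------


def median_polish(
    x: np.ndarray, tol: float = 1e-9, max_iter: int = 50
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array, row sweeps first.

    Returns (overall, row_effects, col_effects, residuals). Iteration stops
    when the maximum absolute change in residuals falls below ``tol`` or
    after ``max_iter`` full sweeps.
    """
    z = np.array(x, dtype=float)
    if z.ndim != 2:
        raise DataValidationError("median_polish expects a 2-D array")
    overall = 0.0
    row = np.zeros(z.shape[0])
    col = np.zeros(z.shape[1])
    for _ in range(max_iter):
        z_prev = z.copy()
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        overall += delta
        col -= delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        overall += delta
        row -= delta
        if np.max(np.abs(z - z_prev)) < tol:
            break
    return overall, row, col, z


def median_polish_summarize(
    probe_em: ExpressionMatrix, probe_to_gene: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Summarize probe-level values to one value per (gene, sample).

    Every probe must map to exactly one gene. The per-sample summary is
    overall + sample effect of the gene's median-polish fit; a single-probe
    gene therefore reproduces the probe's values exactly.
    """
    mapping = pd.Series(probe_to_gene)
    missing = [p for p in probe_em.values.index if p not in mapping.index]
    if missing:
        raise DataValidationError(f"probes with no gene mapping: {missing[:5]}")
    mapping = mapping.loc[probe_em.values.index]
    genes = list(dict.fromkeys(mapping))  # first-appearance order
    rows = np.empty((len(genes), probe_em.values.shape[1]))
    for i, gene in enumerate(genes):
        block = probe_em.values.loc[mapping.index[mapping == gene]].to_numpy(dtype=float)
        overall, _, col_eff, _ = median_polish(block)
        rows[i] = overall + col_eff
    return ExpressionMatrix(
        pd.DataFrame(rows, index=pd.Index(genes, name="feature_id"),
                     columns=probe_em.values.columns),
        scale=probe_em.scale,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes batch correction
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Per-(gene, batch) location/scale estimates and their EB posteriors."""

    batches: list[str]
    gamma_hat: pd.DataFrame      # genes x batches, raw location estimates
    delta_hat: pd.DataFrame      # genes x batches, raw scale (variance)
    gamma_star: pd.DataFrame     # shrunken locations
    delta_star: pd.DataFrame     # shrunken variances
    grand_mean: pd.Series        # per-gene grand mean
    var_pooled: pd.Series        # per-gene pooled residual variance
    gamma_bar: pd.Series         # per-batch normal-prior mean
    t2: pd.Series                # per-batch normal-prior variance
    a_prior: pd.Series           # per-batch inverse-gamma shape
    b_prior: pd.Series           # per-batch inverse-gamma scale
    covariate_columns: list[str]


def _design_matrices(
    annot: SampleAnnotation, sample_ids: Sequence[str], covariates: Sequence[str]
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Batch indicator block and reference-encoded covariate block."""
    tab = annot.table.loc[list(sample_ids)]
    batches = sorted(tab["batch"].unique())
    batch_design = np.column_stack(
        [(tab["batch"] == b).to_numpy(dtype=float) for b in batches])
    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    for cov in covariates:
        if cov not in tab.columns:
            raise DataValidationError(f"covariate {cov!r} absent from annotation")
        series = tab[cov]
        if pd.api.types.is_numeric_dtype(series):
            cov_cols.append(series.to_numpy(dtype=float))
            cov_names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # first level is the reference
                cov_cols.append((series.astype(str) == level).to_numpy(dtype=float))
                cov_names.append(f"{cov}[{level}]")
    cov_design = (np.column_stack(cov_cols) if cov_cols
                  else np.empty((len(tab), 0)))
    return batch_design, batches, cov_design, cov_names


def combat_adjust(
    em: ExpressionMatrix,
    annot: SampleAnnotation,
    covariates: Sequence[str] = ("diagnosis", "sex", "age"),
    conv: float = 1e-4,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Parametric empirical-Bayes location-scale batch correction.

    Each gene is standardized by its fitted grand mean plus covariate effects
    and pooled residual SD; per-batch location and scale are estimated,
    shrunk by iterative posterior updates under normal / inverse-gamma
    priors (relative tolerance ``conv``), removed, and the covariate
    structure restored. Requires >= 2 batches with >= 2 samples each and a
    design not confounded with batch.
    """
    samples = list(em.sample_ids)
    annot_sub = annot.subset(samples)
    batch_design, batches, cov_design, cov_names = _design_matrices(
        annot_sub, samples, covariates)
    if len(batches) < 2:
        raise PipelineError(
            f"batch correction undefined with a single batch ({batches[0]!r}); "
            "run this arm with batch correction skipped")
    n_per_batch = batch_design.sum(axis=0)
    if (n_per_batch < 2).any():
        small = [b for b, n in zip(batches, n_per_batch) if n < 2]
        raise PipelineError(f"batch(es) with < 2 samples: {small}")
    design = np.hstack([batch_design, cov_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the first covariate column that collides with the batch block
        culprit = "covariate design"
        for j, name in enumerate(cov_names):
            cols = np.hstack([batch_design, cov_design[:, : j + 1]])
            if np.linalg.matrix_rank(cols) < cols.shape[1]:
                culprit = name
                break
        raise PipelineError(
            f"design is rank deficient: covariate {culprit!r} is confounded "
            "with batch (or with another covariate)")

    dat = em.values.to_numpy(dtype=float)  # genes x samples
    genes = em.values.index
    n_array = len(samples)
    n_batch = len(batches)

    # least-squares fit of batch means + covariate effects
    b_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # p x genes
    grand_mean = (n_per_batch / n_array) @ b_hat[:n_batch]        # genes
    resid = dat - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)                        # genes
    if (var_pooled <= 0).any():
        raise PipelineError("gene(s) with zero pooled variance; cannot standardize")

    stand_mean = grand_mean[:, None] + (cov_design @ b_hat[n_batch:]).T
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (dat - stand_mean) / sd

    gamma_hat = np.linalg.solve(batch_design.T @ batch_design,
                                batch_design.T @ s_data.T)        # batches x genes
    delta_hat = np.empty_like(gamma_hat)
    for i in range(n_batch):
        cols = batch_design[:, i] == 1
        delta_hat[i] = s_data[:, cols].var(axis=1, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean ** 2) / d_var
    b_prior = (d_mean * d_var + d_mean ** 3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batch):
        cols = batch_design[:, i] == 1
        n_i = cols.sum()
        sdat = s_data[:, cols]
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        for _ in range(10000):  # safety cap; convergence is typically < 100
            g_new = (t2[i] * n_i * gamma_hat[i] + d_old * gamma_bar[i]) / (
                t2[i] * n_i + d_old)
            sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior[i]) / (n_i / 2 + a_prior[i] - 1)
            change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                         np.max(np.abs(d_new - d_old) / d_old))
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        gamma_star[i] = g_old
        delta_star[i] = d_old

    bayes = s_data.copy()
    for i in range(n_batch):
        cols = batch_design[:, i] == 1
        bayes[:, cols] = (bayes[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            delta_star[i])[:, None]
    adjusted = bayes * sd + stand_mean

    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat.T, index=genes, columns=batches),
        delta_hat=pd.DataFrame(delta_hat.T, index=genes, columns=batches),
        gamma_star=pd.DataFrame(gamma_star.T, index=genes, columns=batches),
        delta_star=pd.DataFrame(delta_star.T, index=genes, columns=batches),
        grand_mean=pd.Series(grand_mean, index=genes),
        var_pooled=pd.Series(var_pooled, index=genes),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        t2=pd.Series(t2, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
        covariate_columns=cov_names,
    )
    out = ExpressionMatrix(
        pd.DataFrame(adjusted, index=genes, columns=em.values.columns),
        scale=em.scale,
    )
    return out, model


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(em: ExpressionMatrix, k: int) -> pd.DataFrame:
    """Sample scores on the top-k principal axes of the gene-centered matrix.

    Component signs are fixed by making the largest-magnitude gene loading of
    each axis positive, so scores are reproducible across runs.
    """
    x = em.values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if k > min(n_genes, n_samples):
        raise DataValidationError(
            f"k={k} exceeds min(genes, samples)={min(n_genes, n_samples)}")
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = (vt[:k].T * s[:k])  # samples x k
    for comp in range(k):
        j = int(np.argmax(np.abs(u[:, comp])))
        if u[j, comp] < 0:
            scores[:, comp] *= -1
    return pd.DataFrame(scores, index=em.values.columns,
                        columns=[f"PC{i + 1}" for i in range(k)])
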