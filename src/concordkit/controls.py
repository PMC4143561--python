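"""Control (housekeeping) gene selection from microarray data.

Candidate controls are genes that are well expressed but not saturated
(mean expression inside a log2 window, 8-12 by default) and maximally stable
across samples, measured as the per-gene variance computed within each batch
and averaged across batches. The lowest-variance 2% of the window (ceiling
rounding, so at least one candidate) is returned in ascending-variance order.
The final pick in a real study additionally uses functional annotation; this
module returns the ranked candidate pool only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    DataValidationError,
    ExpressionMatrix,
    PipelineError,
    SampleAnnotation,
)


def batch_averaged_variance(
    em: ExpressionMatrix, annot: SampleAnnotation
) -> pd.DataFrame:
    """Per-gene mean expression and batch-averaged within-batch variance.

    mean_expr pools all samples; per-batch variances use the n-1 denominator
    and are averaged unweighted across batches. Every batch needs >= 2
    samples.
    """
    annot_sub = annot.subset(list(em.sample_ids))
    batch_of = annot_sub.table["batch"]
    variances = []
    for batch in sorted(batch_of.unique()):
        cols = batch_of.index[batch_of == batch]
        if len(cols) < 2:
            raise PipelineError(
                f"batch {batch!r} has {len(cols)} sample(s); variance undefined")
        variances.append(em.values[cols].var(axis=1, ddof=1))
    stab = pd.DataFrame({
        "mean_expr": em.values.mean(axis=1),
        "avg_within_batch_var": pd.concat(variances, axis=1).mean(axis=1),
    })
    stab.index.name = "gene_id"
    return stab


def select_control_candidates(
    stab: pd.DataFrame, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Rank the lowest-variance genes inside the expression window.

    Window bounds are inclusive. Returns ceil(quantile * window size)
    candidates ordered by ascending variance, ties broken by gene id.
    """
    lo, hi = cfg.control_expr_window
    in_window = stab[(stab["mean_expr"] >= lo) & (stab["mean_expr"] <= hi)]
    if in_window.empty:
        raise PipelineError(
            f"no genes with mean expression in [{lo}, {hi}]; cannot select controls")
    n_keep = math.ceil(cfg.control_var_quantile * len(in_window))
    # sort by gene id first so the stable variance sort breaks ties
    # lexicographically, independent of input order
    ranked = in_window.sort_index().sort_values("avg_within_batch_var", kind="stable")
    out = ranked.head(n_keep).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def binned_mean_variance(stab: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Equal-width bins over mean expression; per-bin average mean/variance.

    Empty bins are reported with count 0 (averages NaN). Useful for the
    mean-variance diagnostic showing saturation-driven variance loss at the
    high end of the array range.
    """
    if n_bins < 1:
        raise DataValidationError("n_bins must be >= 1")
    means = stab["mean_expr"].to_numpy(dtype=float)
    lo, hi = means.min(), means.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    # right-inclusive last bin so the maximum lands in bin n_bins - 1
    idx = np.clip(np.digitize(means, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin": b,
            "low": edges[b],
            "high": edges[b + 1],
            "n_genes": int(mask.sum()),
            "mean_expr": float(means[mask].mean()) if mask.any() else np.nan,
            "mean_var": float(stab["avg_within_batch_var"].to_numpy()[mask].mean())
            if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)
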