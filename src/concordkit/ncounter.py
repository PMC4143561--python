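"""nCounter count processing.

Stages, applied independently per cell type:

1. positive-control normalization — each sample is multiplicatively scaled so
   its geometric mean of positive-control counts equals a common target (the
   arithmetic mean of per-sample geometric means, the instrument vendor's
   convention); factors outside the recommended 0.3-3 range are QC-flagged;
2. expression thresholding — the threshold is the median across samples of
   each sample's maximum negative-control count;
3. expressed calls — a gene is called expressed when its median scaled count
   strictly exceeds the threshold;
4. log transform — log2(count + pseudocount), pseudocount 1 by default so
   zero counts map to 0;
5. control-gene normalization — per sample, the mean of the control genes'
   log values is subtracted from every gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    PipelineError,
)


@dataclass
class NormalizationResult:
    factors: pd.Series       # per-sample positive scale factor
    target: float            # common geometric-mean target
    qc_flag: pd.Series       # True where factor outside the recommended bounds


@dataclass
class ExpressionCalls:
    threshold: float
    expressed: pd.Series     # per-gene boolean


def positive_control_normalize(
    cm: CountMatrix, cfg: AnalysisConfig
) -> tuple[CountMatrix, NormalizationResult]:
    """Scale each sample so positive-control geometric means are equal.

    factor_s = target / geomean(positive counts of sample s), with target the
    arithmetic mean of the per-sample geometric means. A zero positive-control
    count makes the geometric mean zero and is an error naming the sample.
    """
    pos = cm.counts.loc[cm.probes_of("positive")].to_numpy(dtype=float)
    zero_cols = (pos <= 0).any(axis=0)
    if zero_cols.any():
        bad = cm.sample_ids[zero_cols][0]
        raise PipelineError(
            f"sample {bad!r} has a zero positive-control count; geometric mean undefined")
    geomeans = np.exp(np.log(pos).mean(axis=0))
    target = float(geomeans.mean())
    factors = pd.Series(target / geomeans, index=cm.sample_ids, name="factor")
    lo, hi = cfg.factor_bounds
    qc = ((factors < lo) | (factors > hi)).rename("qc_flag")
    scaled = CountMatrix(
        counts=cm.counts.astype(float) * factors,
        probe_class=cm.probe_class.copy(),
        run_id=cm.run_id.copy(),
        scaled=True,
    )
    return scaled, NormalizationResult(factors=factors, target=target, qc_flag=qc)


def expression_threshold(cm: CountMatrix) -> float:
    """Median across samples of the per-sample maximum negative-control count."""
    neg = cm.probes_of("negative")
    if not len(neg):
        raise PipelineError("no negative-control probes; threshold undefined")
    maxima = cm.counts.loc[neg].max(axis=0)
    return float(np.median(maxima.to_numpy(dtype=float)))


def call_expressed(cm: CountMatrix, threshold: float) -> ExpressionCalls:
    """Call a gene expressed when its median count strictly exceeds threshold.

    Ties (median exactly equal to the threshold) are called unexpressed.
    """
    if threshold < 0:
        raise DataValidationError("threshold must be >= 0")
    medians = cm.counts.loc[cm.gene_ids].median(axis=1)
    expressed = (medians > threshold).rename("expressed")
    return ExpressionCalls(threshold=float(threshold), expressed=expressed)


def log_counts(cm: CountMatrix, cfg: AnalysisConfig) -> ExpressionMatrix:
    """log2(count + pseudocount) for gene probes (endogenous + housekeeping)."""
    vals = cm.counts.loc[cm.gene_ids].astype(float) + cfg.log_pseudocount
    if (vals.to_numpy() <= 0).any():
        raise PipelineError("log transform undefined: count + pseudocount <= 0")
    return ExpressionMatrix(np.log2(vals), scale="log2")


def control_gene_normalize(
    em: ExpressionMatrix, control_ids: Sequence[str]
) -> ExpressionMatrix:
    """Subtract the per-sample mean of the control genes' log values.

    Control genes themselves are transformed too (they become centered on 0
    when a single control is used).
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise PipelineError("control_gene_normalize requires at least one control id")
    missing = [c for c in control_ids if c not in em.values.index]
    if missing:
        raise PipelineError(f"control gene(s) absent from matrix: {missing}")
    reference = em.values.loc[control_ids].mean(axis=0)
    return ExpressionMatrix(em.values.sub(reference, axis=1), scale=em.scale)


def replicate_concordance(
    a: pd.Series, b: pd.Series, expressed_mask: pd.Series
) -> float:
    """Pearson correlation of two replicate runs over expressed genes."""
    common = a.index.intersection(b.index)
    mask = expressed_mask.reindex(common).fillna(False).astype(bool)
    x = a.loc[common][mask].to_numpy(dtype=float)
    y = b.loc[common][mask].to_numpy(dtype=float)
    if len(x) < 3:
        raise PipelineError(
            f"replicate concordance needs >= 3 expressed genes, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PipelineError("replicate concordance undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])
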