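"""Cross-platform concordance metrics.

The core analysis: map microarray probesets to nCounter genes, then per gene
compute the across-sample Pearson correlation between platforms and the
signal detection slope (OLS of microarray expression values on
control-gene-normalized log nCounter measurements; slope 1 = accurate,
< 1 = compression). Precision is quantified by the standard deviation of all
pairwise between-sample log-ratios of microarray values for two gene sets —
genes called unexpressed by the nCounter, and genes invariant by the
nCounter (variance < 0.1) but unsaturated on the array (median < 11) — and
compared across cell types with the Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    DataValidationError,
    ExpressionMatrix,
    PipelineError,
    ProbeMapTable,
)
from .ncounter import ExpressionCalls

logger = logging.getLogger("concordkit")


# ---------------------------------------------------------------------------
# probe mapping
# ---------------------------------------------------------------------------


def resolve_probe_map(
    pm: ProbeMapTable, seed: int, genes: Sequence[str] | None = None
) -> pd.Series:
    """Choose one probeset per gene: maximal overlap, seeded draw on ties.

    Genes in ``genes`` but absent from the table are excluded with a logged
    warning. Deterministic given the seed (genes processed in sorted order).
    """
    if pm.table.empty:
        raise DataValidationError("probe map table is empty")
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for gene, group in sorted(pm.table.groupby("gene_id"), key=lambda kv: str(kv[0])):
        best = group[group["overlap"] == group["overlap"].max()]
        candidates = sorted(best["probeset_id"].astype(str))
        chosen[gene] = candidates[int(rng.integers(len(candidates)))] \
            if len(candidates) > 1 else candidates[0]
    if genes is not None:
        missing = sorted(set(genes) - set(chosen))
        for g in missing:
            logger.warning("gene %s has no probeset in the map; excluded", g)
        chosen = {g: ps for g, ps in chosen.items() if g in set(genes)}
    return pd.Series(chosen, name="probeset_id")


# ---------------------------------------------------------------------------
# per-gene metrics
# ---------------------------------------------------------------------------


def gene_correlation(
    array_em: ExpressionMatrix,
    nc_em: ExpressionMatrix,
    mapping: pd.Series,
) -> pd.DataFrame:
    """Pearson r per mapped gene across aligned samples.

    Zero variance on either platform makes r undefined for that gene; it is
    reported as missing with a reason rather than dropped.
    """
    if list(array_em.sample_ids) != list(nc_em.sample_ids):
        raise DataValidationError("sample sets/order differ between platforms")
    if len(array_em.sample_ids) < 3:
        raise PipelineError("gene correlation requires >= 3 shared samples")
    rows = []
    for gene, probeset in mapping.items():
        x = nc_em.values.loc[gene].to_numpy(dtype=float)
        y = array_em.values.loc[probeset].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"gene_id": gene, "pearson_r": np.nan,
                         "reason": "zero variance"})
        else:
            rows.append({"gene_id": gene,
                         "pearson_r": float(np.corrcoef(x, y)[0, 1]),
                         "reason": ""})
    return pd.DataFrame(rows).set_index("gene_id")


def signal_detection_slope(
    array_gene: np.ndarray | pd.Series, nc_gene: np.ndarray | pd.Series
) -> tuple[float, float]:
    """OLS of array values (response) on nCounter log values (predictor)."""
    y = np.asarray(array_gene, dtype=float)
    x = np.asarray(nc_gene, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise PipelineError("signal detection slope requires >= 3 paired samples")
    dx = x - x.mean()
    ss = float(dx @ dx)
    if ss == 0:
        raise PipelineError("zero predictor variance; slope undefined")
    slope = float(dx @ (y - y.mean())) / ss
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def pairwise_logratio_sd(gene_values: np.ndarray | pd.Series) -> float:
    """Spread of all ordered between-sample log-ratios of one gene.

    On log2 data the log-ratio of samples i, j is x_i - x_j; the multiset of
    all ordered pairs is mean-zero by symmetry, so its root mean square is
    returned. Analytically this equals sqrt(2) times the sample SD.
    """
    x = np.asarray(gene_values, dtype=float)
    if len(x) < 2:
        raise PipelineError("pairwise log-ratio SD requires >= 2 samples")
    diffs = np.subtract.outer(x, x)
    off = ~np.eye(len(x), dtype=bool)
    return float(np.sqrt(np.mean(diffs[off] ** 2)))


def noise_gene_sets(
    calls: ExpressionCalls,
    nc_norm: ExpressionMatrix,
    array_em: ExpressionMatrix,
    cfg: AnalysisConfig,
    mapping: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """Unexpressed and invariant-but-unsaturated gene sets.

    Set 1: genes called unexpressed. Set 2: expressed genes with
    control-gene-normalized nCounter variance strictly below
    ``invariant_var_max`` and microarray median strictly below
    ``saturation_median_max``.
    """
    genes = [g for g in nc_norm.values.index if g in calls.expressed.index]
    if mapping is None:
        mapping = pd.Series({g: g for g in genes})
    unexpressed, invariant = [], []
    for gene in genes:
        probeset = mapping.get(gene)
        if probeset is None or probeset not in array_em.values.index:
            continue
        if not calls.expressed[gene]:
            unexpressed.append(gene)
            continue
        nc_var = float(nc_norm.values.loc[gene].var(ddof=1))
        array_median = float(array_em.values.loc[probeset].median())
        if nc_var < cfg.invariant_var_max and array_median < cfg.saturation_median_max:
            invariant.append(gene)
    return unexpressed, invariant


def mann_whitney(
    a: np.ndarray | Sequence[float],
    b: np.ndarray | Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Rank-sum U (of the first sample) and two-sided p.

    ``auto`` uses exact enumeration when n_a * n_b <= 400 and the pooled
    data has no ties, otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataValidationError("mann_whitney requires non-empty samples")
    if method == "auto":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "normal"
    if method == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif method == "normal":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise DataValidationError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass
class NoiseSummary:
    """Per-gene pairwise log-ratio SDs for each noise gene set."""

    sds: dict[str, pd.Series] = field(default_factory=dict)  # set name -> SDs


def concordance_table(
    array_em: ExpressionMatrix,
    nc_norm: ExpressionMatrix,
    calls: ExpressionCalls,
    mapping: pd.Series,
    cfg: AnalysisConfig,
) -> tuple[pd.DataFrame, NoiseSummary]:
    """One row per mapped gene plus the per-cell-type noise summary.

    Correlations and slopes are computed for expressed genes only (slope for
    every expressed gene with a defined correlation, so the slope-versus-r
    relation can be examined); ``passes_r_filter`` applies the strict
    r > correlation_min rule.
    """
    rows = []
    corr = gene_correlation(array_em, nc_norm,
                            mapping[[g for g in mapping.index
                                     if calls.expressed.get(g, False)]])
    for gene, probeset in mapping.items():
        if probeset not in array_em.values.index or gene not in nc_norm.values.index:
            continue
        y = array_em.values.loc[probeset]
        x = nc_norm.values.loc[gene]
        expressed = bool(calls.expressed.get(gene, False))
        r = np.nan
        reason = "unexpressed"
        slope = intercept = np.nan
        if expressed:
            r = float(corr.at[gene, "pearson_r"])
            reason = str(corr.at[gene, "reason"])
            if np.isfinite(r) and float(x.std(ddof=1)) > 0:
                slope, intercept = signal_detection_slope(y, x)
        rows.append({
            "gene_id": gene,
            "probeset_id": probeset,
            "expressed": expressed,
            "pearson_r": r,
            "r_missing_reason": reason,
            "slope": slope,
            "intercept": intercept,
            "array_median": float(y.median()),
            "array_variance": float(y.var(ddof=1)),
            "nc_variance": float(x.var(ddof=1)),
            "passes_r_filter": bool(np.isfinite(r) and r > cfg.correlation_min),
        })
    table = pd.DataFrame(rows).set_index("gene_id")

    unexpr, invar = noise_gene_sets(calls, nc_norm, array_em, cfg, mapping)
    summary = NoiseSummary()
    for name, gene_set in (("unexpressed", unexpr), ("invariant", invar)):
        sds = {g: pairwise_logratio_sd(array_em.values.loc[mapping[g]])
               for g in gene_set}
        summary.sds[name] = pd.Series(sds, dtype=float, name="pairwise_logratio_sd")
    return table, summary


def compare_noise(summaries: Mapping[str, NoiseSummary]) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparison of noise SDs across cell types."""
    rows = []
    cell_types = sorted(summaries)
    for gene_set in ("unexpressed", "invariant"):
        for i, ct_a in enumerate(cell_types):
            for ct_b in cell_types[i + 1:]:
                a = summaries[ct_a].sds.get(gene_set, pd.Series(dtype=float))
                b = summaries[ct_b].sds.get(gene_set, pd.Series(dtype=float))
                if a.empty or b.empty:
                    continue
                u, p = mann_whitney(a.to_numpy(), b.to_numpy())
                rows.append({
                    "gene_set": gene_set, "cell_type_a": ct_a, "cell_type_b": ct_b,
                    "n_a": len(a), "n_b": len(b),
                    "median_sd_a": float(a.median()), "median_sd_b": float(b.median()),
                    "u_statistic": u, "p_value": p,
                })
    return pd.DataFrame(rows)
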