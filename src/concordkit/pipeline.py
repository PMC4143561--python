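"""End-to-end orchestration and truth-recovery reporting.

Stage order per cell type mirrors the analysis design: nCounter processing
(positive-control scaling, negative-control thresholding, expressed calls,
log transform) -> microarray preprocessing (quantile normalization, optional
median-polish summarization, empirical-Bayes batch correction, PCA) ->
control-gene selection from the microarray -> control-gene normalization of
the nCounter logs -> cross-platform concordance and noise metrics. Cell
types are processed independently end-to-end; single-batch arms must be run
with batch correction skipped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import concordance as cc
from . import controls as ctl
from . import microarray as ma
from . import ncounter as nc
from .core import (
    AnalysisConfig,
    CountMatrix,
    ExpressionMatrix,
    PipelineError,
    ProbeMapTable,
    SampleAnnotation,
    read_annotation,
    read_expression_matrix,
    read_probe_map,
    read_rcc,
    validate_dataset,
    write_expression_matrix,
)
from .simulate import SimConfig, TruthSet, simulate_dataset

logger = logging.getLogger("concordkit")

N_CONTROL_GENES = 2  # controls used for nCounter normalization per arm


@dataclass
class CellTypeResult:
    """Everything the pipeline computes for one cell-type arm."""

    cell_type: str
    norm: nc.NormalizationResult
    threshold: float
    calls: nc.ExpressionCalls
    nc_log: ExpressionMatrix
    nc_norm: ExpressionMatrix
    control_genes: list[str]
    stability: pd.DataFrame
    candidates: pd.DataFrame
    bins: pd.DataFrame
    array_processed: ExpressionMatrix
    batch_model: ma.BatchModel | None
    pca: pd.DataFrame
    concordance: pd.DataFrame
    noise: cc.NoiseSummary
    mapping: pd.Series


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record_stage(self, name: str, seconds: float) -> None:
        self.stages[name] = {"status": "done", "seconds": round(seconds, 3)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise PipelineError(f"manifest lists outputs that were not written: {missing}")


def _stage(manifest: RunManifest | None, name: str, t0: float) -> None:
    if manifest is not None:
        manifest.record_stage(name, time.perf_counter() - t0)


def process_cell_type(
    counts: CountMatrix,
    array: ExpressionMatrix,
    annot: SampleAnnotation,
    probe_map: ProbeMapTable,
    cfg: AnalysisConfig,
    skip_combat: bool = False,
    cell_type: str = "",
) -> CellTypeResult:
    """Run every pipeline stage for one cell-type arm (in memory)."""
    report = validate_dataset(annot, counts=counts, expression=None)
    blocking = report.blocking_for("all")
    if blocking:
        raise PipelineError(
            f"[validate:{cell_type}] {'; '.join(f.message for f in blocking)}")
    if not skip_combat and report.blocking_for("batch_correction"):
        msgs = "; ".join(f.message for f in report.blocking_for("batch_correction"))
        raise PipelineError(f"[batch_correction:{cell_type}] {msgs}")
    n_batches = annot.table["batch"].nunique()
    if n_batches < 2 and not skip_combat:
        raise PipelineError(
            f"[batch_correction:{cell_type}] single batch; batch correction is "
            "undefined — rerun with this arm's batch correction skipped")

    # nCounter side
    scaled, norm = nc.positive_control_normalize(counts, cfg)
    threshold = nc.expression_threshold(scaled)
    calls = nc.call_expressed(scaled, threshold)
    nc_log = nc.log_counts(scaled, cfg)

    # microarray side
    array_qn = ma.quantile_normalize(array)
    batch_model = None
    if skip_combat:
        array_proc = array_qn
    else:
        array_proc, batch_model = ma.combat_adjust(array_qn, annot)
    pca = ma.pca_scores(array_proc, k=min(2, len(array_proc.sample_ids)))

    # probeset resolution and array genes
    mapping = cc.resolve_probe_map(probe_map, cfg.seed,
                                   genes=list(counts.gene_ids))
    mapping = mapping[[g for g in mapping.index
                       if mapping[g] in set(array_proc.feature_ids)]]

    # control selection on the processed array, reported at gene level
    reverse = {ps: g for g, ps in mapping.items()}
    array_genes = array_proc.subset_features(list(mapping.to_numpy()))
    array_genes = ExpressionMatrix(
        array_genes.values.rename(index=reverse), scale=array_genes.scale)
    stability = ctl.batch_averaged_variance(array_genes, annot)
    candidates = ctl.select_control_candidates(stability, cfg)
    bins = ctl.binned_mean_variance(stability, cfg.n_bins)
    control_genes = list(candidates.index[:N_CONTROL_GENES])

    # normalize nCounter logs to the selected controls and compare platforms
    nc_norm = nc.control_gene_normalize(nc_log, control_genes)
    samples = list(array_proc.sample_ids)
    nc_norm_aligned = nc_norm.subset_samples(samples)
    table, noise = cc.concordance_table(array_proc, nc_norm_aligned, calls,
                                        mapping, cfg)
    return CellTypeResult(
        cell_type=cell_type, norm=norm, threshold=threshold, calls=calls,
        nc_log=nc_log, nc_norm=nc_norm, control_genes=control_genes,
        stability=stability, candidates=candidates, bins=bins,
        array_processed=array_proc, batch_model=batch_model, pca=pca,
        concordance=table, noise=noise, mapping=mapping,
    )


def process_dataset(
    dataset: Mapping, cfg: AnalysisConfig | None = None
) -> dict[str, CellTypeResult]:
    """Process every cell type of an in-memory dataset.

    Single-batch arms automatically run without batch correction, mirroring
    an RMA-only arm.
    """
    cfg = cfg or AnalysisConfig()
    annot: SampleAnnotation = dataset["annotation"]
    counts: CountMatrix = dataset["counts"]
    array: ExpressionMatrix = dataset["array"]
    results: dict[str, CellTypeResult] = {}
    for ct in annot.cell_types:
        annot_ct = annot.for_cell_type(ct)
        samples = list(annot_ct.sample_ids)
        single_batch = annot_ct.table["batch"].nunique() < 2
        results[ct] = process_cell_type(
            counts.subset_samples(samples), array.subset_samples(samples),
            annot_ct, dataset["probe_map"], cfg,
            skip_combat=single_batch, cell_type=ct)
    return results


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------


def run_pipeline(
    config_path: str | Path,
    input_dir: str | Path,
    output_dir: str | Path,
    skip_combat: Sequence[str] = (),
) -> RunManifest:
    """File-based end-to-end run; returns the serialized manifest.

    ``skip_combat`` lists cell types whose microarray arm skips batch
    correction (required for single-batch arms). Any stage error aborts with
    the stage name and offending entity in the message.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    for required in (Path(config_path), input_dir / "annotation.csv",
                     input_dir / "array.tsv", input_dir / "probe_map.csv",
                     input_dir / "rcc"):
        if not required.exists():
            raise PipelineError(f"required input missing: {required}")
    cfg = AnalysisConfig.from_file(config_path)
    manifest = RunManifest(config=json.loads(json.dumps(cfg.__dict__, default=list)),
                           seed=cfg.seed,
                           inputs={"config": str(config_path), "input_dir": str(input_dir)})
    t0 = time.perf_counter()
    annot = read_annotation(input_dir / "annotation.csv")
    counts = read_rcc(sorted((input_dir / "rcc").glob("*.csv")))
    array = read_expression_matrix(input_dir / "array.tsv")
    probe_map = read_probe_map(input_dir / "probe_map.csv")
    _stage(manifest, "read_inputs", t0)

    output_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, CellTypeResult] = {}
    for ct in annot.cell_types:
        t0 = time.perf_counter()
        annot_ct = annot.for_cell_type(ct)
        samples = list(annot_ct.sample_ids)
        res = process_cell_type(
            counts.subset_samples(samples), array.subset_samples(samples),
            annot_ct, probe_map, cfg,
            skip_combat=ct in set(skip_combat), cell_type=ct)
        results[ct] = res
        ct_dir = output_dir / ct
        ct_dir.mkdir(exist_ok=True)
        _write_cell_type(res, ct_dir, manifest)
        _stage(manifest, f"cell_type:{ct}", t0)

    t0 = time.perf_counter()
    noise_cmp = cc.compare_noise({ct: r.noise for ct, r in results.items()})
    path = output_dir / "noise_comparison.csv"
    noise_cmp.to_csv(path, index=False)
    manifest.outputs.append(str(path))
    _stage(manifest, "noise_comparison", t0)
    manifest.to_json(output_dir / "manifest.json")
    return manifest


def _write_cell_type(res: CellTypeResult, ct_dir: Path, manifest: RunManifest) -> None:
    def _save(obj, name, **kw):
        path = ct_dir / name
        obj.to_csv(path, **kw)
        manifest.outputs.append(str(path))

    factors = pd.DataFrame({"factor": res.norm.factors, "qc_flag": res.norm.qc_flag})
    factors.index.name = "sample_id"
    _save(factors, "factors.csv")
    (ct_dir / "threshold.txt").write_text(f"{res.threshold!r}\n")
    manifest.outputs.append(str(ct_dir / "threshold.txt"))
    calls = res.calls.expressed.to_frame()
    calls.index.name = "gene_id"
    _save(calls, "calls.tsv", sep="\t")
    write_expression_matrix(res.nc_log, ct_dir / "nc_log.tsv")
    write_expression_matrix(res.nc_norm, ct_dir / "nc_norm.tsv")
    write_expression_matrix(res.array_processed, ct_dir / "array_processed.tsv")
    manifest.outputs += [str(ct_dir / n) for n in
                         ("nc_log.tsv", "nc_norm.tsv", "array_processed.tsv")]
    pca = res.pca.copy()
    pca.index.name = "sample_id"
    _save(pca, "pca_scores.csv")
    _save(res.stability, "stability.csv")
    _save(res.candidates, "control_candidates.csv")
    _save(res.bins, "mean_variance_bins.csv", index=False)
    _save(res.concordance, "concordance.csv")
    for name, sds in res.noise.sds.items():
        frame = sds.to_frame()
        frame.index.name = "gene_id"
        _save(frame, f"noise_{name}.csv")


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------


def _classify_abundance(truth: TruthSet, cell_type: str) -> pd.DataFrame:
    """Per-gene truth class for one arm: mid_range / above_knee / below_knee."""
    cfg = truth.config
    samples = truth.annotation.for_cell_type(cell_type).sample_ids
    med = truth.theta[list(samples)].median(axis=1)
    cls = pd.Series("mid_range", index=truth.gene_ids)
    cls[med > cfg.knee_high] = "above_knee"
    cls[med < cfg.knee_low] = "below_knee"
    # restrict mid-range to comfortably inside the knees so the per-gene
    # regressions are dominated by the linear regime
    inner = (med >= cfg.knee_low + 1) & (med <= cfg.knee_high - 1)
    cls[(cls == "mid_range") & ~inner] = "near_knee"
    cls[truth.gene_flags["unexpressed"]] = "unexpressed"
    return pd.DataFrame({"theta_median": med, "abundance_class": cls})


def recovery_report(
    results: Mapping[str, CellTypeResult], truth: TruthSet
) -> dict:
    """Compare pipeline estimates against simulation truth.

    Reports, per cell type: the expressed-call confusion matrix and derived
    sensitivity/specificity; the median pairwise log-ratio SD of
    nCounter-unexpressed genes against its floor-model prediction
    sqrt(2) * sigma_t; the control-candidate hit rate; and median signal
    detection slopes of mid-range (r-filter passing) and above-knee genes.
    Pooled across arms: the median mid-range slope versus the generative
    beta_mid.
    """
    cfg = truth.config
    truth_cts = set(truth.annotation.table["cell_type"])
    per_ct: dict[str, dict] = {}
    pooled_mid: list[float] = []
    pooled_above: list[float] = []
    for ct, res in results.items():
        if ct not in truth_cts:
            raise PipelineError(f"cell type {ct!r} absent from the truth record")
        if set(res.calls.expressed.index) != set(truth.gene_ids):
            raise PipelineError(
                f"gene set of {ct!r} results does not match the truth record")
        truth_expr = truth.expressed_truth()
        called = res.calls.expressed.reindex(truth_expr.index)
        tp = int((called & truth_expr).sum())
        tn = int((~called & ~truth_expr).sum())
        fp = int((called & ~truth_expr).sum())
        fn = int((~called & truth_expr).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")

        sigma = cfg.cell_type(ct).noise_sd
        unexpr_sds = res.noise.sds.get("unexpressed", pd.Series(dtype=float))
        med_sd = float(unexpr_sds.median()) if len(unexpr_sds) else float("nan")
        expected_sd = float(np.sqrt(2.0) * sigma)

        hits = truth.gene_flags.loc[
            [g for g in res.candidates.index if g in truth.gene_flags.index],
            "control"]
        hit_rate = float(hits.mean()) if len(hits) else float("nan")

        classes = _classify_abundance(truth, ct)
        table = res.concordance.join(classes, how="left")
        mid = table[(table["abundance_class"] == "mid_range")
                    & table["passes_r_filter"]]["slope"].dropna()
        above = table[(table["abundance_class"] == "above_knee")
                      & table["expressed"]]["slope"].dropna()
        pooled_mid += list(mid)
        pooled_above += list(above)
        per_ct[ct] = {
            "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
            "call_sensitivity": sens,
            "call_specificity": spec,
            "median_unexpressed_sd": med_sd,
            "expected_unexpressed_sd": expected_sd,
            "sd_ratio": med_sd / expected_sd if expected_sd else float("nan"),
            "control_hit_rate": hit_rate,
            "n_candidates": int(len(res.candidates)),
            "median_mid_range_slope": float(mid.median()) if len(mid) else float("nan"),
            "n_mid_range": int(len(mid)),
            "median_above_knee_slope": float(above.median()) if len(above) else float("nan"),
            "n_above_knee": int(len(above)),
        }
    return {
        "beta_mid": cfg.beta_mid,
        "pooled_median_mid_range_slope":
            float(np.median(pooled_mid)) if pooled_mid else float("nan"),
        "pooled_median_above_knee_slope":
            float(np.median(pooled_above)) if pooled_above else float("nan"),
        "slope_abs_error":
            float(abs(np.median(pooled_mid) - cfg.beta_mid)) if pooled_mid else float("nan"),
        "per_cell_type": per_ct,
    }


def end_to_end(
    sim_cfg: SimConfig | None = None, cfg: AnalysisConfig | None = None
) -> tuple[dict, dict[str, CellTypeResult], dict]:
    """Simulate, process every arm, and score recovery against truth."""
    sim_cfg = sim_cfg or SimConfig()
    dataset = simulate_dataset(sim_cfg)
    results = process_dataset(dataset, cfg)
    report = recovery_report(results, dataset["truth"])
    return dataset, results, report
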