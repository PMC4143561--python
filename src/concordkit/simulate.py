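"""Paired microarray / nCounter dataset simulator.

The generator emulates the study design the pipeline assumes: several
leukocyte cell types, each with multiple diagnoses, processed in microarray
batches and nCounter runs. True per-(gene, sample) log2 abundances theta are
drawn per cell type; the nCounter observes Poisson counts proportional to
linear abundance (plus a small hybridization background), while the
microarray observes a compressed, probe-affinity-shifted, batch-shifted and
noisy transform of theta.

Compression is continuous piecewise-linear in theta: slope ``beta_mid``
between the knees L and H, reduced slopes below L (background floor) and
above H (saturation), and a constant floor for unexpressed genes, which carry
measurement noise only. Unexpressed genes have theta = -inf (zero molecules);
designated control genes have zero diagnosis effect and zero biological
variance, so they are truly invariant before measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    CountMatrix,
    DataValidationError,
    ExpressionMatrix,
    ProbeMapTable,
    SampleAnnotation,
    write_annotation,
    write_expression_matrix,
    write_probe_map,
    write_rcc,
)

UNEXPRESSED = -np.inf  # theta sentinel: zero molecules


@dataclass(frozen=True)
class CellTypeConfig:
    """One simulated cell-type arm.

    noise_sd is the microarray measurement noise sd (log2 units) for the arm;
    the per-arm defaults of :class:`SimConfig` emulate the tissue-specific
    noise pattern of leukocyte subsets (CD4 quieter than CD14/CD16).
    """

    name: str
    noise_sd: float
    n_batches: int = 2
    diagnoses: tuple[str, ...] = ("HC", "AAV", "IBD")
    n_per_group: int = 14


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters; defaults are the study conditions."""

    n_genes: int = 200
    n_unexpressed: int = 40
    n_controls: int = 5
    cell_types: tuple[CellTypeConfig, ...] = (
        CellTypeConfig("CD4", noise_sd=0.15, n_batches=2),
        CellTypeConfig("CD14", noise_sd=0.30, n_batches=2),
        CellTypeConfig("CD16", noise_sd=0.30, n_batches=1),
    )
    # biology
    effect_sd: float = 0.8        # per-(gene, diagnosis) log2 effect sd (tau)
    bio_sd: float = 1.0           # per-(gene, sample) biological variation sd
    sex_effect_sd: float = 0.2    # per-gene log2 shift applied to male samples
    age_effect_sd: float = 0.005  # per-gene log2 slope per year of age
    baseline_range: tuple[float, float] = (3.0, 12.0)
    control_baseline_range: tuple[float, float] = (8.5, 9.5)
    # microarray response
    beta_mid: float = 0.5
    beta_low: float = 0.25
    beta_high: float = 0.35
    knee_low: float = 4.0         # L, log2 abundance units
    knee_high: float = 10.0       # H
    response_at_knee_low: float = 6.5  # array value at theta = L
    array_floor: float = 5.0      # constant array level of unexpressed genes
    probe_affinity_sd: float = 0.5
    probes_per_gene: int = 4      # probe-level simulation only
    # microarray batches
    batch_shift_sd: float = 0.5   # per-(gene, batch) additive shift sd
    batch_scale_sd: float = 0.1   # lognormal sd of per-(gene, batch) noise scale
    # nCounter
    n_runs: int = 6
    run_eff_sd: float = 0.15      # lognormal sd of per-run efficiency e_r
    capture_scale: float = 2.0    # expected counts per unit linear abundance
    neg_background_rate: float = 4.0
    n_neg_probes: int = 6
    pos_control_concs: tuple[float, ...] = (8.0, 32.0, 128.0, 512.0, 2048.0, 8192.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("effect_sd", "bio_sd", "sex_effect_sd", "age_effect_sd",
                     "probe_affinity_sd", "batch_shift_sd", "batch_scale_sd",
                     "run_eff_sd", "neg_background_rate"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be >= 0")
        if self.beta_mid <= 0:
            raise DataValidationError("beta_mid must be > 0")
        if not self.knee_low < self.knee_high:
            raise DataValidationError("knee_low must be < knee_high")
        if self.capture_scale <= 0:
            raise DataValidationError("capture_scale must be > 0")
        if self.n_unexpressed + self.n_controls > self.n_genes:
            raise DataValidationError("n_unexpressed + n_controls must be <= n_genes")
        for ct in self.cell_types:
            if ct.noise_sd < 0:
                raise DataValidationError(f"noise_sd of {ct.name} must be >= 0")
            if ct.n_batches < 1 or ct.n_per_group < 1:
                raise DataValidationError(f"invalid sample design for {ct.name}")

    def cell_type(self, name: str) -> CellTypeConfig:
        for ct in self.cell_types:
            if ct.name == name:
                return ct
        raise KeyError(name)


@dataclass
class TruthSet:
    """True abundances, gene flags and the full generative record."""

    theta: pd.DataFrame           # genes x samples; -inf = unexpressed
    gene_flags: pd.DataFrame      # columns: unexpressed, control (bool)
    annotation: SampleAnnotation
    config: SimConfig
    record: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> pd.Index:
        return self.theta.index

    def expressed_truth(self) -> pd.Series:
        return ~self.gene_flags["unexpressed"]


def compression_response(theta: np.ndarray | float, cfg: SimConfig) -> np.ndarray:
    """Continuous piecewise-linear microarray response g(theta).

    Slope ``beta_mid`` on [L, H], ``beta_low`` below L and ``beta_high``
    above H, anchored at g(L) = ``response_at_knee_low``. Monotone
    non-decreasing for positive slopes. ``-inf`` maps to the constant floor.
    """
    th = np.asarray(theta, dtype=float)
    L, H = cfg.knee_low, cfg.knee_high
    g = np.where(
        th < L,
        cfg.response_at_knee_low + cfg.beta_low * (th - L),
        np.where(
            th <= H,
            cfg.response_at_knee_low + cfg.beta_mid * (th - L),
            cfg.response_at_knee_low + cfg.beta_mid * (H - L) + cfg.beta_high * (th - H),
        ),
    )
    return np.where(np.isneginf(th), cfg.array_floor, g)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # one top-level seed; independent child streams per stage
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def simulate_truth(cfg: SimConfig) -> TruthSet:
    """Draw the true abundance matrix and all generative effects."""
    rng = _rng(cfg, 0)
    genes = pd.Index([f"G{i:03d}" for i in range(cfg.n_genes)], name="gene_id")

    perm = rng.permutation(cfg.n_genes)
    control_idx = set(perm[: cfg.n_controls])
    unexpressed_idx = set(perm[cfg.n_controls: cfg.n_controls + cfg.n_unexpressed])
    flags = pd.DataFrame(
        {
            "unexpressed": [i in unexpressed_idx for i in range(cfg.n_genes)],
            "control": [i in control_idx for i in range(cfg.n_genes)],
        },
        index=genes,
    )

    # sample frame: per cell type, per diagnosis
    rows = []
    for ct in cfg.cell_types:
        for diag in ct.diagnoses:
            for i in range(ct.n_per_group):
                rows.append((ct.name, diag, i))
    sample_ids, cell_type_col, diag_col = [], [], []
    for ct_name, diag, i in rows:
        sample_ids.append(f"{ct_name}_{diag}_{i:02d}")
        cell_type_col.append(ct_name)
        diag_col.append(diag)
    n_samples = len(sample_ids)
    sexes = rng.choice(["F", "M"], size=n_samples)
    ages = rng.integers(20, 71, size=n_samples)
    runs = [f"run{1 + (i % cfg.n_runs)}" for i in rng.permutation(n_samples)]

    # batch: stratified round-robin within (cell type, diagnosis) so batches
    # are balanced for diagnosis and never confounded with it
    batches = []
    counters: dict[tuple[str, str], int] = {}
    for ct_name, diag in zip(cell_type_col, diag_col):
        nb = cfg.cell_type(ct_name).n_batches
        k = counters.get((ct_name, diag), 0)
        counters[(ct_name, diag)] = k + 1
        batches.append(f"{ct_name}_b{1 + (k % nb)}")

    annot = SampleAnnotation(pd.DataFrame(
        {
            "cell_type": cell_type_col,
            "diagnosis": diag_col,
            "batch": batches,
            "run": runs,
            "sex": sexes,
            "age": ages.astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    record: dict = {"baselines": {}, "diag_effects": {}, "sex_effects": {},
                    "age_effects": {}, "batch_shifts": {}, "batch_scales": {},
                    "run_efficiency": {}, "affinity": None, "probe_offsets": None}

    # per-gene microarray probe affinity (shared across cell types: one platform)
    record["affinity"] = pd.Series(
        rng.normal(0.0, cfg.probe_affinity_sd, size=cfg.n_genes), index=genes)
    record["probe_offsets"] = pd.DataFrame(
        rng.normal(0.0, cfg.probe_affinity_sd, size=(cfg.n_genes, cfg.probes_per_gene)),
        index=genes, columns=[f"p{k + 1}" for k in range(cfg.probes_per_gene)])

    run_names = sorted({r for r in runs}, key=lambda r: int(r[3:]))
    record["run_efficiency"] = pd.Series(
        np.exp(rng.normal(0.0, cfg.run_eff_sd, size=len(run_names))), index=run_names)

    lo, hi = cfg.baseline_range
    clo, chi = cfg.control_baseline_range
    theta = pd.DataFrame(np.nan, index=genes, columns=pd.Index(sample_ids, name="sample_id"))
    is_ctrl = flags["control"].to_numpy()
    is_unexp = flags["unexpressed"].to_numpy()

    for ct in cfg.cell_types:
        base = rng.uniform(lo, hi, size=cfg.n_genes)
        base[is_ctrl] = rng.uniform(clo, chi, size=int(is_ctrl.sum()))
        base[is_unexp] = UNEXPRESSED
        record["baselines"][ct.name] = pd.Series(base, index=genes)

        eff = pd.DataFrame(0.0, index=genes, columns=list(ct.diagnoses))
        for diag in ct.diagnoses[1:]:  # first diagnosis is the reference level
            draw = rng.normal(0.0, cfg.effect_sd, size=cfg.n_genes)
            draw[is_ctrl] = 0.0
            eff[diag] = draw
        record["diag_effects"][ct.name] = eff

        sex_eff = rng.normal(0.0, cfg.sex_effect_sd, size=cfg.n_genes)
        sex_eff[is_ctrl] = 0.0
        record["sex_effects"][ct.name] = pd.Series(sex_eff, index=genes)
        age_eff = rng.normal(0.0, cfg.age_effect_sd, size=cfg.n_genes)
        age_eff[is_ctrl] = 0.0
        record["age_effects"][ct.name] = pd.Series(age_eff, index=genes)

        ct_mask = annot.table["cell_type"] == ct.name
        ct_samples = annot.table.index[ct_mask]
        bio = rng.normal(0.0, cfg.bio_sd, size=(cfg.n_genes, len(ct_samples)))
        bio[is_ctrl, :] = 0.0
        for j, sid in enumerate(ct_samples):
            row = annot.table.loc[sid]
            th = (base
                  + eff[row["diagnosis"]].to_numpy()
                  + (sex_eff if row["sex"] == "M" else 0.0)
                  + age_eff * (float(row["age"]) - 40.0)
                  + bio[:, j])
            th[is_unexp] = UNEXPRESSED
            theta[sid] = th

        # microarray batch effects for this arm
        batch_names = sorted(annot.table.loc[ct_mask, "batch"].unique())
        record["batch_shifts"][ct.name] = pd.DataFrame(
            rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, len(batch_names))),
            index=genes, columns=batch_names)
        record["batch_scales"][ct.name] = pd.DataFrame(
            np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=(cfg.n_genes, len(batch_names)))),
            index=genes, columns=batch_names)

    return TruthSet(theta=theta, gene_flags=flags, annotation=annot,
                    config=cfg, record=record)


def simulate_ncounter(truth: TruthSet, cfg: SimConfig | None = None) -> CountMatrix:
    """Poisson counts: endogenous ~ Poisson(e_r * capture * 2^theta + bg)."""
    cfg = cfg or truth.config
    rng = _rng(cfg, 1)
    annot = truth.annotation.table
    samples = truth.theta.columns
    eff = truth.record["run_efficiency"]
    e_r = np.array([eff[annot.loc[s, "run"]] for s in samples])

    linear = np.exp2(truth.theta.to_numpy())  # exp2(-inf) = 0: no molecules
    lam_gene = e_r[None, :] * cfg.capture_scale * linear + cfg.neg_background_rate
    gene_counts = rng.poisson(lam_gene)

    pos_ids = [f"POS_{chr(65 + i)}" for i in range(len(cfg.pos_control_concs))]
    lam_pos = e_r[None, :] * cfg.capture_scale * np.array(cfg.pos_control_concs)[:, None]
    pos_counts = rng.poisson(lam_pos)

    neg_ids = [f"NEG_{i + 1}" for i in range(cfg.n_neg_probes)]
    neg_counts = rng.poisson(cfg.neg_background_rate,
                             size=(cfg.n_neg_probes, len(samples)))

    probe_ids = list(truth.gene_ids) + pos_ids + neg_ids
    counts = pd.DataFrame(
        np.vstack([gene_counts, pos_counts, neg_counts]),
        index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    probe_class = pd.Series(
        ["housekeeping" if truth.gene_flags.at[g, "control"] else "endogenous"
         for g in truth.gene_ids]
        + ["positive"] * len(pos_ids) + ["negative"] * len(neg_ids),
        index=probe_ids, name="probe_class")
    run_id = annot.loc[samples, "run"].rename("run_id")
    return CountMatrix(counts=counts, probe_class=probe_class, run_id=run_id)


def simulate_microarray(
    truth: TruthSet,
    cfg: SimConfig | None = None,
    probe_level: bool = False,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Microarray values a_g + g(theta) + batch shift + scaled noise.

    Returns the matrix and a feature -> probeset mapping. With
    ``probe_level=True``, emits ``probes_per_gene`` probes per gene with
    probe-specific offsets and independent noise, for median-polish
    summarization tests; the mapping then maps probes to probesets.
    """
    cfg = cfg or truth.config
    rng = _rng(cfg, 3 if probe_level else 2)
    annot = truth.annotation.table
    samples = truth.theta.columns
    genes = truth.gene_ids
    g_theta = compression_response(truth.theta.to_numpy(), cfg)
    affinity = truth.record["affinity"].to_numpy()

    shift = np.zeros((len(genes), len(samples)))
    scale = np.ones((len(genes), len(samples)))
    sigma = np.empty(len(samples))
    for j, sid in enumerate(samples):
        row = annot.loc[sid]
        ct = row["cell_type"]
        shift[:, j] = truth.record["batch_shifts"][ct][row["batch"]].to_numpy()
        scale[:, j] = truth.record["batch_scales"][ct][row["batch"]].to_numpy()
        sigma[j] = cfg.cell_type(ct).noise_sd

    base = affinity[:, None] + g_theta + shift
    if not probe_level:
        eps = rng.normal(0.0, 1.0, size=base.shape) * scale * sigma[None, :]
        values = pd.DataFrame(base + eps,
                              index=pd.Index([f"PS_{g}" for g in genes], name="feature_id"),
                              columns=samples)
        mapping = pd.Series({f"PS_{g}": f"PS_{g}" for g in genes}, name="probeset_id")
        return ExpressionMatrix(values), mapping

    offsets = truth.record["probe_offsets"]
    blocks, probe_ids, probe_to_ps = [], [], {}
    for k, col in enumerate(offsets.columns):
        eps = rng.normal(0.0, 1.0, size=base.shape) * scale * sigma[None, :]
        blocks.append(base + offsets[col].to_numpy()[:, None] + eps)
        for g in genes:
            pid = f"PS_{g}_{col}"
            probe_ids.append(pid)
            probe_to_ps[pid] = f"PS_{g}"
    # interleave so probes of one gene are adjacent
    n_g, n_p = len(genes), len(offsets.columns)
    stacked = np.empty((n_g * n_p, len(samples)))
    ordered_ids = []
    for i, g in enumerate(genes):
        for k in range(n_p):
            stacked[i * n_p + k] = blocks[k][i]
            ordered_ids.append(f"PS_{g}_{offsets.columns[k]}")
    values = pd.DataFrame(stacked, index=pd.Index(ordered_ids, name="feature_id"),
                          columns=samples)
    mapping = pd.Series({pid: probe_to_ps[pid] for pid in ordered_ids},
                        name="probeset_id")
    return ExpressionMatrix(values), mapping


def make_probe_map(truth: TruthSet) -> ProbeMapTable:
    """One probeset per gene with full target-region overlap."""
    table = pd.DataFrame({
        "gene_id": list(truth.gene_ids),
        "probeset_id": [f"PS_{g}" for g in truth.gene_ids],
        "overlap": 100.0,
    })
    return ProbeMapTable(table)


def simulate_dataset(cfg: SimConfig) -> dict:
    """Convenience wrapper: truth, counts, array matrix, probe map."""
    truth = simulate_truth(cfg)
    counts = simulate_ncounter(truth, cfg)
    array, _ = simulate_microarray(truth, cfg)
    return {
        "truth": truth,
        "counts": counts,
        "array": array,
        "probe_map": make_probe_map(truth),
        "annotation": truth.annotation,
    }


def write_dataset(dataset: dict, out_dir: str | Path,
                  analysis_cfg: AnalysisConfig | None = None) -> dict[str, Path]:
    """Write a simulated dataset as plain-text files under ``out_dir``.

    Layout: ``rcc/<sample>.csv`` count files, ``array.tsv``,
    ``annotation.csv``, ``probe_map.csv``, ``truth_theta.tsv``,
    ``truth_flags.csv`` and ``config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: TruthSet = dataset["truth"]
    paths: dict[str, Path] = {}
    write_rcc(dataset["counts"], out_dir / "rcc")
    paths["rcc"] = out_dir / "rcc"
    paths["array"] = out_dir / "array.tsv"
    write_expression_matrix(dataset["array"], paths["array"])
    paths["annotation"] = out_dir / "annotation.csv"
    write_annotation(dataset["annotation"], paths["annotation"])
    paths["probe_map"] = out_dir / "probe_map.csv"
    write_probe_map(dataset["probe_map"], paths["probe_map"])
    paths["truth_theta"] = out_dir / "truth_theta.tsv"
    df = truth.theta.copy()
    df.index.name = "gene_id"
    df.to_csv(paths["truth_theta"], sep="\t")
    paths["truth_flags"] = out_dir / "truth_flags.csv"
    truth.gene_flags.to_csv(paths["truth_flags"])
    if analysis_cfg is not None:
        paths["config"] = out_dir / "config.yaml"
        analysis_cfg.to_file(paths["config"])
    for name, p in paths.items():
        logging.getLogger("concordkit").info("wrote %s -> %s", name, p)
    return paths
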