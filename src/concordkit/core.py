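"""Core data containers, plain-text I/O and dataset validation.

The pipeline exchanges three kinds of tables:

* expression matrices — features x samples, log2 scale, tab-separated with
  feature ids in the first column and sample ids in the header row;
* nCounter count matrices — probes x samples with a per-probe class label
  (endogenous / positive / negative / housekeeping) and a per-sample run id,
  read from a simplified RCC dialect (one CSV per sample holding a
  ``CodeClass,Name,Count`` section);
* sample annotation — one CSV row per sample with cell type, diagnosis,
  batch, run, sex and age.

Missing values are not supported anywhere; readers fail fast and name the
offending cell.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("concordkit")

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")

#: probe classes whose counts represent genes under study
GENE_CLASSES = ("endogenous", "housekeeping")

ANNOTATION_COLUMNS = ("cell_type", "diagnosis", "batch", "run", "sex", "age")


class PipelineError(Exception):
    """Base class for all errors raised by concordkit."""


class ParseError(PipelineError):
    """A file could not be parsed; the message names the location."""


class DataValidationError(PipelineError):
    """An in-memory dataset violates a structural invariant."""


def _check_unique(ids: Iterable, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = sorted(map(str, idx[idx.duplicated()].unique()))
        raise DataValidationError(f"duplicate {what}: {', '.join(dupes)}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """nCounter counts, probes x samples, with probe classes and run ids.

    Raw counts must be nonnegative integers (molecule counts); after
    positive-control scaling the values become real-valued, recorded by
    ``scaled=True``.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    run_id: pd.Series
    scaled: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "probe ids")
        _check_unique(self.counts.columns, "sample ids")
        self.probe_class = self.probe_class.reindex(self.counts.index)
        if self.probe_class.isna().any():
            missing = list(self.probe_class.index[self.probe_class.isna()])
            raise DataValidationError(f"probe class missing for: {missing}")
        bad = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if bad:
            raise DataValidationError(f"unknown probe classes: {sorted(bad)}")
        self.run_id = self.run_id.reindex(self.counts.columns)
        if self.run_id.isna().any():
            missing = list(self.run_id.index[self.run_id.isna()])
            raise DataValidationError(f"run id missing for samples: {missing}")
        vals = self.counts.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataValidationError("counts contain non-finite values")
        if (vals < 0).any():
            raise DataValidationError("counts contain negative values")
        if not self.scaled and not np.array_equal(vals, np.floor(vals)):
            raise DataValidationError("raw counts must be integral")
        if not len(self.probes_of("positive")):
            raise DataValidationError("no positive-control probes present")
        if not len(self.probes_of("negative")):
            raise DataValidationError("no negative-control probes present")

    # -- convenience -------------------------------------------------------

    def probes_of(self, probe_class: str) -> pd.Index:
        return self.counts.index[self.probe_class == probe_class]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index[self.probe_class.isin(GENE_CLASSES)]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise DataValidationError(f"unknown sample ids: {sorted(missing)}")
        return CountMatrix(
            counts=self.counts[sample_ids].copy(),
            probe_class=self.probe_class.copy(),
            run_id=self.run_id.loc[sample_ids].copy(),
            scaled=self.scaled,
        )


@dataclass
class ExpressionMatrix:
    """Real-valued features x samples matrix (log2 scale by default)."""

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise DataValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataValidationError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise DataValidationError(f"unknown sample ids: {sorted(missing)}")
        return ExpressionMatrix(self.values[sample_ids].copy(), scale=self.scale)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        feature_ids = list(feature_ids)
        missing = set(feature_ids) - set(self.values.index)
        if missing:
            raise DataValidationError(f"unknown feature ids: {sorted(missing)}")
        return ExpressionMatrix(self.values.loc[feature_ids].copy(), scale=self.scale)


@dataclass
class SampleAnnotation:
    """Per-sample covariates: cell type, diagnosis, batch, run, sex, age."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids in annotation")
        missing = set(ANNOTATION_COLUMNS) - set(self.table.columns)
        if missing:
            raise DataValidationError(f"annotation missing columns: {sorted(missing)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise DataValidationError(f"samples absent from annotation: {sorted(missing)}")
        return SampleAnnotation(self.table.loc[sample_ids].copy())

    def for_cell_type(self, cell_type: str) -> "SampleAnnotation":
        mask = self.table["cell_type"] == cell_type
        if not mask.any():
            raise DataValidationError(f"no samples annotated with cell type {cell_type!r}")
        return SampleAnnotation(self.table[mask].copy())


@dataclass
class ProbeMapTable:
    """Mapping of nCounter genes to microarray probesets with overlap scores."""

    table: pd.DataFrame  # columns gene_id, probeset_id, overlap

    def __post_init__(self) -> None:
        need = {"gene_id", "probeset_id", "overlap"}
        missing = need - set(self.table.columns)
        if missing:
            raise DataValidationError(f"probe map missing columns: {sorted(missing)}")
        pairs = self.table[["gene_id", "probeset_id"]]
        if pairs.duplicated().any():
            raise DataValidationError("duplicate (gene_id, probeset_id) pairs in probe map")
        if (self.table["overlap"].to_numpy(dtype=float) < 0).any():
            raise DataValidationError("probe map overlap scores must be >= 0")


@dataclass
class AnalysisConfig:
    """Every numeric threshold used by the analysis.

    Defaults are the thresholds of the study design: control genes are drawn
    from mean microarray expression 8-12 log2 units and the lowest-variance 2%
    of that window, positive-control scale factors are flagged outside 0.3-3,
    genes are called nCounter-invariant below variance 0.1, microarray values
    are treated as saturated at median >= 11, and the concordance filter keeps
    genes with Pearson r > 0.5.
    """

    control_expr_window: tuple[float, float] = (8.0, 12.0)
    control_var_quantile: float = 0.02
    factor_bounds: tuple[float, float] = (0.3, 3.0)
    invariant_var_max: float = 0.1
    saturation_median_max: float = 11.0
    correlation_min: float = 0.5
    log_pseudocount: float = 1.0
    n_bins: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.control_expr_window = tuple(float(v) for v in self.control_expr_window)
        self.factor_bounds = tuple(float(v) for v in self.factor_bounds)
        lo, hi = self.control_expr_window
        if not lo < hi:
            raise DataValidationError("control_expr_window must satisfy low < high")
        if not 0 < self.control_var_quantile < 1:
            raise DataValidationError("control_var_quantile must be in (0, 1)")
        blo, bhi = self.factor_bounds
        if not blo < bhi:
            raise DataValidationError("factor_bounds must satisfy low < high")
        for name in ("invariant_var_max", "saturation_median_max",
                     "correlation_min", "log_pseudocount"):
            if not math.isfinite(float(getattr(self, name))):
                raise DataValidationError(f"{name} must be finite")
        if self.log_pseudocount < 0:
            raise DataValidationError("log_pseudocount must be >= 0")
        if int(self.n_bins) < 1:
            raise DataValidationError("n_bins must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys in {path}: {sorted(unknown)}")
        for key in ("control_expr_window", "factor_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["control_expr_window"] = list(self.control_expr_window)
        data["factor_bounds"] = list(self.factor_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a tab-separated features x samples matrix.

    First column holds feature ids, header row holds sample ids. Any
    non-numeric cell (including 'NA') raises :class:`ParseError` naming the
    row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], f"sample ids in {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    _check_unique(raw.index, f"feature ids in {path}")
    vals = np.empty(raw.shape)
    # cell-wise float() parse: exact round-trip and precise error locations
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw.iloc[:, j]):
            try:
                vals[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at row {raw.index[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None
    values = pd.DataFrame(vals, index=raw.index, columns=raw.columns)
    values.index.name = raw.index.name or "feature_id"
    return ExpressionMatrix(values, scale=scale)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the reader's format at full float precision."""
    df = em.values.copy()
    df.index.name = df.index.name or "feature_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# simplified RCC dialect
# ---------------------------------------------------------------------------

_RCC_HEADER = ("codeclass", "name", "count")


def _parse_rcc(path: Path) -> tuple[str, dict[str, tuple[str, int]]]:
    """Parse one simplified RCC file -> (run id, probe -> (class, count))."""
    run = "run1"
    probes: dict[str, tuple[str, int]] = {}
    in_summary = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = [p.strip() for p in line.rstrip("\n").split(",")]
            if not any(parts):
                continue
            low = [p.lower() for p in parts]
            if not in_summary:
                if low[:3] == list(_RCC_HEADER):
                    in_summary = True
                elif low[0] == "runid" and len(parts) > 1:
                    run = parts[1]
                else:
                    logger.debug("ignoring RCC header line %d of %s", lineno, path)
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected CodeClass,Name,Count row")
            code, name, count_str = parts[0], parts[1], parts[2]
            probe_class = code.lower()
            if probe_class not in PROBE_CLASSES:
                raise ParseError(f"{path}:{lineno}: unknown CodeClass {code!r}")
            try:
                count = float(count_str)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric count {count_str!r}") from None
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count for probe {name!r}")
            if count != int(count):
                raise ParseError(f"{path}:{lineno}: fractional count for probe {name!r}")
            if name in probes:
                raise ParseError(f"{path}:{lineno}: duplicate probe {name!r}")
            probes[name] = (probe_class, int(count))
    if not in_summary:
        raise ParseError(f"{path}: no CodeClass,Name,Count section found")
    return run, probes


def read_rcc(paths: Sequence[str | Path]) -> CountMatrix:
    """Read one simplified RCC file per sample and align probes by name.

    The sample id is the file stem. A probe present in one sample but missing
    from another raises an alignment error naming the probe.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise DataValidationError("read_rcc requires at least one file")
    per_sample: dict[str, dict[str, tuple[str, int]]] = {}
    runs: dict[str, str] = {}
    for path in paths:
        sample = path.stem
        if sample in per_sample:
            raise DataValidationError(f"duplicate sample id {sample!r} from {path}")
        runs[sample], per_sample[sample] = _parse_rcc(path)
    first_sample = paths[0].stem
    probe_order = list(per_sample[first_sample])
    probe_set = set(probe_order)
    for sample, probes in per_sample.items():
        extra = set(probes) - probe_set
        missing = probe_set - set(probes)
        if extra or missing:
            name = sorted(extra or missing)[0]
            raise DataValidationError(
                f"probe {name!r} not shared by all samples (sample {sample!r})"
            )
    classes = {}
    for name in probe_order:
        seen = {per_sample[s][name][0] for s in per_sample}
        if len(seen) > 1:
            raise DataValidationError(f"probe {name!r} has inconsistent CodeClass: {sorted(seen)}")
        classes[name] = seen.pop()
    counts = pd.DataFrame(
        {s: [per_sample[s][name][1] for name in probe_order] for s in per_sample},
        index=pd.Index(probe_order, name="probe_id"),
    )
    return CountMatrix(
        counts=counts,
        probe_class=pd.Series(classes, name="probe_class"),
        run_id=pd.Series(runs, name="run_id"),
    )


def write_rcc(cm: CountMatrix, out_dir: str | Path) -> list[Path]:
    """Write one simplified RCC CSV per sample under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sample in cm.sample_ids:
        path = out_dir / f"{sample}.csv"
        with open(path, "w") as fh:
            fh.write(f"RunID,{cm.run_id[sample]}\n")
            fh.write("CodeClass,Name,Count\n")
            for probe in cm.counts.index:
                val = cm.counts.at[probe, sample]
                text = repr(float(val)) if cm.scaled else str(int(val))
                fh.write(f"{cm.probe_class[probe].capitalize()},{probe},{text}\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# annotation and probe map I/O
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> SampleAnnotation:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in table.columns:
        raise ParseError(f"annotation {path} lacks a sample_id column")
    table = table.set_index("sample_id")
    if "age" in table.columns:
        try:
            table["age"] = pd.to_numeric(table["age"], errors="raise")
        except (ValueError, TypeError):
            raise ParseError(f"annotation {path}: non-numeric age value") from None
    return SampleAnnotation(table)


def write_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    df = annot.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


def read_probe_map(path: str | Path) -> ProbeMapTable:
    table = pd.read_csv(path)
    return ProbeMapTable(table)


def write_probe_map(pm: ProbeMapTable, path: str | Path) -> None:
    pm.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset validation
# ---------------------------------------------------------------------------


@dataclass
class Finding:
    stage: str  # "all" or a specific pipeline stage, e.g. "batch_correction"
    blocking: bool
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.blocking for f in self.findings)

    def blocking_for(self, stage: str) -> list[Finding]:
        return [f for f in self.findings if f.blocking and f.stage in ("all", stage)]

    def messages(self) -> list[str]:
        return [f"[{f.stage}]{' BLOCKING' if f.blocking else ''} {f.message}"
                for f in self.findings]


def validate_dataset(
    annot: SampleAnnotation,
    counts: CountMatrix | None = None,
    expression: ExpressionMatrix | None = None,
) -> ValidationReport:
    """Cross-check matrices against the annotation; report-only.

    Blocking findings: sample ids present in a matrix but absent from the
    annotation (or vice versa), missing covariate values, and — for the batch
    correction stage only — batches with fewer than two samples.
    """
    report = ValidationReport()
    annot_ids = set(annot.sample_ids)
    matrices = []
    if counts is not None:
        matrices.append(("counts", set(counts.sample_ids)))
    if expression is not None:
        matrices.append(("expression", set(expression.sample_ids)))
    for name, ids in matrices:
        for sid in sorted(ids - annot_ids):
            report.findings.append(Finding(
                "all", True, f"sample {sid!r} in {name} matrix absent from annotation"))
        for sid in sorted(annot_ids - ids):
            report.findings.append(Finding(
                "all", True, f"annotated sample {sid!r} absent from {name} matrix"))
    for col in ANNOTATION_COLUMNS:
        vals = annot.table[col]
        bad = vals.isna() | (vals.astype(str).str.strip() == "")
        for sid in annot.table.index[bad]:
            report.findings.append(Finding(
                "batch_correction", True,
                f"sample {sid!r} has missing covariate {col!r}"))
    for batch, group in annot.table.groupby("batch"):
        if len(group) < 2:
            report.findings.append(Finding(
                "batch_correction", True,
                f"batch {batch!r} has only {len(group)} sample(s)"))
    return report
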