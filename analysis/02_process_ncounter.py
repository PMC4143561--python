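#!/usr/bin/env python
"""nCounter processing per cell-type arm.

Positive-control geometric-mean normalization (factors checked against the
0.3-3 range), negative-control expression thresholds, expressed/unexpressed
calls and the log2 count matrix. Outputs under results/ncounter/<arm>/.
"""

from pathlib import Path

import pandas as pd

import concordkit as ck

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "results" / "dataset"


def main() -> None:
    cfg = ck.AnalysisConfig.from_file(DATASET / "config.yaml")
    annot = ck.read_annotation(DATASET / "annotation.csv")
    counts = ck.read_rcc(sorted((DATASET / "rcc").glob("*.csv")))
    for ct in annot.cell_types:
        samples = list(annot.for_cell_type(ct).sample_ids)
        cm = counts.subset_samples(samples)
        scaled, norm = ck.positive_control_normalize(cm, cfg)
        threshold = ck.expression_threshold(scaled)
        calls = ck.call_expressed(scaled, threshold)
        log = ck.log_counts(scaled, cfg)
        out = ROOT / "results" / "ncounter" / ct
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"factor": norm.factors, "qc_flag": norm.qc_flag}) \
            .rename_axis("sample_id").to_csv(out / "factors.csv")
        (out / "threshold.txt").write_text(f"{threshold!r}\n")
        calls.expressed.to_frame().rename_axis("gene_id") \
            .to_csv(out / "calls.tsv", sep="\t")
        ck.write_expression_matrix(log, out / "nc_log.tsv")
        print(f"{ct}: threshold {threshold:.2f} counts, "
              f"{int(calls.expressed.sum())}/{len(calls.expressed)} genes expressed, "
              f"{int(norm.qc_flag.sum())} samples QC-flagged")


if __name__ == "__main__":
    main()
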