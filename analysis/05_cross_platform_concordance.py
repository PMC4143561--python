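#!/usr/bin/env python
"""Cross-platform concordance: the core analysis.

Per arm: nCounter logs normalized to the two selected control genes, then
per-gene Pearson correlation and signal detection slope of microarray
values on control-gene-normalized counts, plus the pairwise log-ratio noise
of unexpressed and invariant genes, compared across arms by Mann-Whitney.
Outputs under results/concordance/.
"""

from pathlib import Path

import pandas as pd

import concordkit as ck

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "results" / "dataset"


def main() -> None:
    cfg = ck.AnalysisConfig.from_file(DATASET / "config.yaml")
    annot = ck.read_annotation(DATASET / "annotation.csv")
    probe_map = ck.read_probe_map(DATASET / "probe_map.csv")
    mapping = ck.resolve_probe_map(probe_map, cfg.seed)
    noise = {}
    for ct in annot.cell_types:
        array = ck.read_expression_matrix(
            ROOT / "results" / "microarray" / ct / "array_processed.tsv")
        nc_log = ck.read_expression_matrix(
            ROOT / "results" / "ncounter" / ct / "nc_log.tsv")
        calls_df = pd.read_csv(ROOT / "results" / "ncounter" / ct / "calls.tsv",
                               sep="\t", index_col=0)
        calls = ck.ExpressionCalls(threshold=float("nan"),
                                   expressed=calls_df["expressed"].astype(bool))
        cand = pd.read_csv(
            ROOT / "results" / "controls" / ct / "control_candidates.csv",
            index_col=0)
        controls = list(cand.index[:2])
        nc_norm = ck.control_gene_normalize(nc_log, controls)
        table, summary = ck.concordance_table(
            array, nc_norm.subset_samples(list(array.sample_ids)),
            calls, mapping, cfg)
        noise[ct] = summary
        out = ROOT / "results" / "concordance"
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{ct}_concordance.csv")
        for name, sds in summary.sds.items():
            sds.to_frame().rename_axis("gene_id") \
                .to_csv(out / f"{ct}_noise_{name}.csv")
        passing = table[table["passes_r_filter"]]
        print(f"{ct}: controls {controls}; "
              f"{len(passing)}/{int(table['expressed'].sum())} expressed genes "
              f"pass r > {cfg.correlation_min}; "
              f"median slope {passing['slope'].median():.3f}; "
              f"median unexpressed-gene SD "
              f"{summary.sds['unexpressed'].median():.3f}")
    cmp = ck.compare_noise(noise)
    cmp.to_csv(ROOT / "results" / "concordance" / "noise_comparison.csv",
               index=False)
    for _, row in cmp[cmp["gene_set"] == "unexpressed"].iterrows():
        print(f"  noise {row['cell_type_a']} vs {row['cell_type_b']}: "
              f"U = {row['u_statistic']:.0f}, p = {row['p_value']:.2e}")


if __name__ == "__main__":
    main()
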