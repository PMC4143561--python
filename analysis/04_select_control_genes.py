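#!/usr/bin/env python
"""Control-gene selection from the processed microarray data.

Per arm: batch-averaged within-batch variances, the 8-12 log2 window, the
lowest-variance 2% candidate pool, and the binned mean-variance diagnostic
(which shows the variance dip at very high expression that motivates the
window's upper bound). Outputs under results/controls/<arm>/.
"""

from pathlib import Path

import concordkit as ck

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "results" / "dataset"


def main() -> None:
    cfg = ck.AnalysisConfig.from_file(DATASET / "config.yaml")
    annot = ck.read_annotation(DATASET / "annotation.csv")
    probe_map = ck.read_probe_map(DATASET / "probe_map.csv")
    for ct in annot.cell_types:
        annot_ct = annot.for_cell_type(ct)
        em = ck.read_expression_matrix(
            ROOT / "results" / "microarray" / ct / "array_processed.tsv")
        mapping = ck.resolve_probe_map(probe_map, cfg.seed)
        reverse = {ps: g for g, ps in mapping.items()}
        gene_em = ck.ExpressionMatrix(em.values.rename(index=reverse))
        stab = ck.batch_averaged_variance(gene_em, annot_ct)
        cand = ck.select_control_candidates(stab, cfg)
        bins = ck.binned_mean_variance(stab, cfg.n_bins)
        out = ROOT / "results" / "controls" / ct
        out.mkdir(parents=True, exist_ok=True)
        stab.to_csv(out / "stability.csv")
        cand.to_csv(out / "control_candidates.csv")
        bins.to_csv(out / "mean_variance_bins.csv", index=False)
        lo, hi = cfg.control_expr_window
        n_window = int(((stab["mean_expr"] >= lo)
                        & (stab["mean_expr"] <= hi)).sum())
        print(f"{ct}: {n_window} genes in [{lo}, {hi}] window -> "
              f"candidates {', '.join(cand.index)}")


if __name__ == "__main__":
    main()
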