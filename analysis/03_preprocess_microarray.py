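#!/usr/bin/env python
"""Microarray preprocessing per cell-type arm.

Quantile normalization, empirical-Bayes batch correction with diagnosis,
sex and age preserved (skipped for single-batch arms, which stay
normalization-only), and PCA scores for batch inspection. Outputs under
results/microarray/<arm>/.
"""

from pathlib import Path

import concordkit as ck

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "results" / "dataset"


def main() -> None:
    annot = ck.read_annotation(DATASET / "annotation.csv")
    array = ck.read_expression_matrix(DATASET / "array.tsv")
    for ct in annot.cell_types:
        annot_ct = annot.for_cell_type(ct)
        em = array.subset_samples(list(annot_ct.sample_ids))
        qn = ck.quantile_normalize(em)
        single_batch = annot_ct.table["batch"].nunique() < 2
        if single_batch:
            processed, note = qn, "single batch - batch correction skipped"
        else:
            processed, model = ck.combat_adjust(qn, annot_ct)
            shrink = (model.gamma_star.abs().mean() / model.gamma_hat.abs().mean())
            note = (f"{len(model.batches)} batches corrected "
                    f"(mean location shrinkage {shrink.mean():.2f})")
        out = ROOT / "results" / "microarray" / ct
        out.mkdir(parents=True, exist_ok=True)
        ck.write_expression_matrix(qn, out / "array_qn.tsv")
        ck.write_expression_matrix(processed, out / "array_processed.tsv")
        ck.pca_scores(processed, 2).rename_axis("sample_id") \
            .to_csv(out / "pca_scores.csv")
        print(f"{ct}: {note}")


if __name__ == "__main__":
    main()
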