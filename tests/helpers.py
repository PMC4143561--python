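"""Independent oracles used by the test suite.

These stay deliberately naive (explicit loops, long iteration budgets) so
they check the package implementations without sharing code with them.
"""

import statistics

import numpy as np
import pandas as pd

import concordkit as ck


def median_polish_oracle(x, sweeps=50, tol=1e-9):
    """Brute-force Tukey median polish: scalar loops, row sweeps first.

    Implements the declared fitting procedure naively (alternating sweeps
    until the residuals move less than ``tol`` or the sweep cap is reached)
    and returns the per-sample summaries overall + column effect.
    """
    z = [list(map(float, row)) for row in x]
    n_rows, n_cols = len(z), len(z[0])
    overall = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    for _ in range(sweeps):
        before = [row[:] for row in z]
        for i in range(n_rows):
            m = statistics.median(z[i])
            row_eff[i] += m
            for j in range(n_cols):
                z[i][j] -= m
        m = statistics.median(col_eff)
        overall += m
        for j in range(n_cols):
            col_eff[j] -= m
        for j in range(n_cols):
            m = statistics.median([z[i][j] for i in range(n_rows)])
            col_eff[j] += m
            for i in range(n_rows):
                z[i][j] -= m
        m = statistics.median(row_eff)
        overall += m
        for i in range(n_rows):
            row_eff[i] -= m
        moved = max(abs(z[i][j] - before[i][j])
                    for i in range(n_rows) for j in range(n_cols))
        if moved < tol:
            break
    return [overall + c for c in col_eff]


def make_annotated_matrix(rng, n_genes=50, batch_sizes=(15, 15),
                          batch_shift=0.0, diag_effect=0.0,
                          diagnoses=("HC", "AAV", "IBD")):
    """Random annotated expression matrix with optional injected effects."""
    n_samples = sum(batch_sizes)
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    batch, diag = [], []
    for bi, size in enumerate(batch_sizes):
        for k in range(size):
            batch.append(f"b{bi + 1}")
            diag.append(diagnoses[k % len(diagnoses)])
    vals = rng.normal(8.0, 1.0, size=(n_genes, n_samples))
    for j in range(n_samples):
        if batch[j] != "b1":
            vals[:, j] += batch_shift
        if diag[j] == diagnoses[1]:
            vals[:, j] += diag_effect
    annot = ck.SampleAnnotation(pd.DataFrame(
        {
            "cell_type": "X",
            "diagnosis": diag,
            "batch": batch,
            "run": "r1",
            "sex": rng.choice(["F", "M"], n_samples),
            "age": rng.integers(20, 71, n_samples),
        },
        index=pd.Index(samples, name="sample_id"),
    ))
    em = ck.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
    return em, annot
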