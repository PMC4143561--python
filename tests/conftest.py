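import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import concordkit as ck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_run():
    """One full end-to-end run at the default study conditions."""
    dataset, results, report = ck.end_to_end(ck.SimConfig(seed=1))
    return {"dataset": dataset, "results": results, "report": report}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_counts(gene_counts, pos_counts=None, neg_counts=None, runs=None,
                gene_classes=None):
    """Build a small CountMatrix from dicts of probe -> per-sample counts.

    Adds one positive and one negative probe if none are given (the
    container requires both classes). Samples are named s0, s1, ...
    """
    genes = pd.DataFrame(gene_counts).T  # rows = genes
    n_samples = genes.shape[1]
    samples = [f"s{j}" for j in range(n_samples)]
    genes.columns = samples
    pos = pd.DataFrame(pos_counts or {"POS_A": [100] * n_samples}).T
    neg = pd.DataFrame(neg_counts or {"NEG_1": [0] * n_samples}).T
    pos.columns = samples
    neg.columns = samples
    counts = pd.concat([genes, pos, neg])
    classes = gene_classes or {g: "endogenous" for g in genes.index}
    probe_class = pd.Series(
        {**classes,
         **{p: "positive" for p in pos.index},
         **{n: "negative" for n in neg.index}})
    run_id = pd.Series(runs or {s: "run1" for s in samples})
    return ck.CountMatrix(counts=counts, probe_class=probe_class, run_id=run_id)
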