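import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import concordkit as ck
from helpers import make_annotated_matrix, median_polish_oracle


def em_from(cols, index=None):
    df = pd.DataFrame(cols)
    if index is not None:
        df.index = index
    else:
        df.index = [f"f{i}" for i in range(len(df))]
    return ck.ExpressionMatrix(df)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        em = em_from({"s1": [4.0, 1.0, 3.0], "s2": [4.0, 1.0, 3.0]})
        out = ck.quantile_normalize(em)
        np.testing.assert_allclose(out.values, em.values)

    def test_hand_worked_rank_mean_example(self):
        em = em_from({"s1": [4.0, 1.0, 3.0], "s2": [2.0, 5.0, 6.0]})
        out = ck.quantile_normalize(em)
        np.testing.assert_allclose(out.values["s1"], [5.0, 1.5, 4.0])
        np.testing.assert_allclose(out.values["s2"], [1.5, 4.0, 5.0])

    def test_ties_take_mean_of_spanned_quantiles(self):
        em = em_from({"s1": [1.0, 1.0, 2.0], "s2": [1.0, 2.0, 3.0]})
        out = ck.quantile_normalize(em)
        # reference quantiles (1, 1.5, 2.5); the tied pair spans the first two
        np.testing.assert_allclose(out.values["s1"], [1.25, 1.25, 2.5])
        np.testing.assert_allclose(out.values["s2"], [1.0, 1.5, 2.5])

    def test_single_sample_rejected(self):
        with pytest.raises(ck.PipelineError, match="2 samples"):
            ck.quantile_normalize(em_from({"s1": [1.0, 2.0]}))

    @given(st.integers(0, 10_000), st.integers(2, 8), st.integers(2, 40))
    def test_columns_share_sorted_values_and_idempotence(self, seed, m, n):
        rng = np.random.default_rng(seed)
        em = em_from({f"s{j}": rng.normal(8, 2, n) for j in range(m)})
        out = ck.quantile_normalize(em)
        x = out.values.to_numpy()
        ref = np.sort(x[:, 0])
        for j in range(1, m):
            np.testing.assert_allclose(np.sort(x[:, j]), ref, atol=1e-12)
        again = ck.quantile_normalize(out)
        np.testing.assert_allclose(again.values.to_numpy(), x, atol=1e-12)


class TestMedianPolish:
    def test_additive_matrix_recovered_exactly(self):
        row = np.array([0.0, 1.0, -2.0])
        col = np.array([5.0, 7.0, 6.0, 8.0])
        x = row[:, None] + col[None, :]
        overall, r, c, resid = ck.median_polish(x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        np.testing.assert_allclose(overall + c, col, atol=1e-12)

    def test_single_probe_gene_passes_through(self):
        em = em_from({"s1": [3.0], "s2": [9.0]}, index=["p1"])
        out = ck.median_polish_summarize(em, {"p1": "g1"})
        np.testing.assert_allclose(out.values.loc["g1"], [3.0, 9.0])

    def test_outlier_cell_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8, 1, size=(3, 3))
        x[1, 2] += 10.0
        em = em_from({f"s{j}": x[:, j] for j in range(3)},
                     index=[f"p{i}" for i in range(3)])
        out = ck.median_polish_summarize(em, {f"p{i}": "g" for i in range(3)})
        expected = median_polish_oracle(x)
        np.testing.assert_allclose(out.values.loc["g"], expected, atol=1e-6)

    def test_probe_offset_absorbed_into_probe_effect(self):
        # shifting a probe that already carries the largest effect leaves the
        # median row effect — and hence the summaries — unchanged; a shift
        # that crosses the median row effect only moves the overall constant,
        # so between-sample differences are invariant in every case
        rng = np.random.default_rng(4)
        x = rng.normal(8, 1, size=(5, 6))
        top = int(np.argmax(x.mean(axis=1)))
        shifted = x.copy()
        shifted[top] += 7.5
        mapping = {f"p{i}": "g" for i in range(5)}
        a = ck.median_polish_summarize(
            em_from({f"s{j}": x[:, j] for j in range(6)},
                    index=[f"p{i}" for i in range(5)]), mapping)
        b = ck.median_polish_summarize(
            em_from({f"s{j}": shifted[:, j] for j in range(6)},
                    index=[f"p{i}" for i in range(5)]), mapping)
        np.testing.assert_allclose(a.values.loc["g"], b.values.loc["g"], atol=1e-6)
        crossed = x.copy()
        crossed[int(np.argmin(x.mean(axis=1)))] += 7.5
        c = ck.median_polish_summarize(
            em_from({f"s{j}": crossed[:, j] for j in range(6)},
                    index=[f"p{i}" for i in range(5)]), mapping)
        np.testing.assert_allclose(np.diff(c.values.loc["g"]),
                                   np.diff(a.values.loc["g"]), atol=1e-6)

    def test_probe_without_gene_mapping_rejected(self):
        em = em_from({"s1": [1.0, 2.0], "s2": [2.0, 1.0]},
                     index=["p1", "p2"])
        with pytest.raises(ck.DataValidationError, match="p2"):
            ck.median_polish_summarize(em, {"p1": "g1"})


class TestCombat:
    def test_single_batch_is_an_error(self, rng):
        em, annot = make_annotated_matrix(rng, batch_sizes=(10,))
        with pytest.raises(ck.PipelineError, match="single batch"):
            ck.combat_adjust(em, annot)

    def test_additive_batch_shift_removed(self, rng):
        em, annot = make_annotated_matrix(rng, n_genes=500,
                                          batch_sizes=(50, 50), batch_shift=2.0)
        adj, _ = ck.combat_adjust(em, annot)
        b1 = annot.table.index[annot.table["batch"] == "b1"]
        b2 = annot.table.index[annot.table["batch"] == "b2"]
        gap = (adj.values[list(b2)].mean(axis=1)
               - adj.values[list(b1)].mean(axis=1)).abs()
        assert gap.median() < 0.1

    def test_balanced_diagnosis_effect_preserved(self, rng):
        em, annot = make_annotated_matrix(rng, n_genes=500,
                                          batch_sizes=(50, 50),
                                          batch_shift=2.0, diag_effect=1.0)
        adj, _ = ck.combat_adjust(em, annot)
        aav = annot.table.index[annot.table["diagnosis"] == "AAV"]
        hc = annot.table.index[annot.table["diagnosis"] == "HC"]
        effect = (adj.values[list(aav)].mean(axis=1)
                  - adj.values[list(hc)].mean(axis=1))
        assert effect.median() == pytest.approx(1.0, rel=0.10)

    def test_near_identity_without_batch_effect(self, rng):
        em, annot = make_annotated_matrix(rng, n_genes=400,
                                          batch_sizes=(60, 60), batch_shift=0.0)
        adj, _ = ck.combat_adjust(em, annot)
        rms = np.sqrt(np.mean((adj.values.to_numpy() - em.values.to_numpy()) ** 2))
        assert rms < 0.05

    def test_confounded_covariate_names_collision(self, rng):
        em, annot = make_annotated_matrix(rng, batch_sizes=(10, 10))
        annot.table["diagnosis"] = np.where(annot.table["batch"] == "b1",
                                            "HC", "AAV")
        with pytest.raises(ck.PipelineError, match="diagnosis"):
            ck.combat_adjust(em, annot)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_reference_eb_implementation(self, rng, tmp_path):
        """Agreement with the Bioconductor parametric ComBat on the same data."""
        em, annot = make_annotated_matrix(rng, n_genes=40, batch_sizes=(15, 15),
                                          batch_shift=1.0, diag_effect=0.5)
        em.values.to_csv(tmp_path / "dat.csv")
        annot.table.to_csv(tmp_path / "annot.csv")
        script = tmp_path / "oracle.R"
        script.write_text(
            'dat <- as.matrix(read.csv("dat.csv", row.names=1, check.names=FALSE))\n'
            'annot <- read.csv("annot.csv", row.names=1, check.names=FALSE)\n'
            "suppressMessages(library(sva))\n"
            "mod <- model.matrix(~ diagnosis + sex + age, data=annot)\n"
            "out <- ComBat(dat=dat, batch=factor(annot$batch), mod=mod)\n"
            'write.csv(out, "r_out.csv")\n')
        subprocess.run(["Rscript", script.name], cwd=tmp_path, check=True,
                       capture_output=True)
        reference = pd.read_csv(tmp_path / "r_out.csv", index_col=0)
        adj, _ = ck.combat_adjust(em, annot)
        # both sides iterate the posterior updates to relative tolerance
        # 1e-4, so agreement is expected to that precision
        np.testing.assert_allclose(adj.values.to_numpy(),
                                   reference.to_numpy(), atol=1e-4)


class TestPca:
    def test_duplicated_sample_gets_identical_scores(self, rng):
        vals = rng.normal(0, 1, size=(20, 5))
        vals[:, 4] = vals[:, 3]
        em = em_from({f"s{j}": vals[:, j] for j in range(5)})
        scores = ck.pca_scores(em, 2)
        np.testing.assert_allclose(scores.loc["s3"], scores.loc["s4"], atol=1e-9)

    def test_rank_one_data_has_flat_second_component(self, rng):
        direction = rng.normal(0, 1, size=10)
        weights = rng.normal(0, 2, size=6)
        vals = np.outer(direction, weights)
        em = em_from({f"s{j}": vals[:, j] for j in range(6)})
        scores = ck.pca_scores(em, 2)
        assert scores["PC2"].var() == pytest.approx(0.0, abs=1e-16)

    def test_batch_shift_separates_on_first_component(self, rng):
        from sklearn.metrics import silhouette_score

        em, annot = make_annotated_matrix(rng, n_genes=200,
                                          batch_sizes=(20, 20), batch_shift=3.0)
        scores = ck.pca_scores(em, 2)
        labels = annot.table.loc[scores.index, "batch"]
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0
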