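import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import concordkit as ck

CFG = ck.AnalysisConfig()


def pm(rows):
    return ck.ProbeMapTable(pd.DataFrame(
        rows, columns=["gene_id", "probeset_id", "overlap"]))


class TestResolveProbeMap:
    def test_best_overlap_wins(self):
        table = pm([("g1", "psA", 30.0), ("g1", "psB", 80.0)])
        assert ck.resolve_probe_map(table, seed=0)["g1"] == "psB"

    def test_tie_resolved_reproducibly(self):
        table = pm([("g1", "psA", 50.0), ("g1", "psB", 50.0)])
        picks = {ck.resolve_probe_map(table, seed=42)["g1"] for _ in range(5)}
        assert len(picks) == 1

    def test_unmapped_gene_excluded_with_warning(self, caplog):
        table = pm([("g1", "psA", 10.0)])
        with caplog.at_level("WARNING", logger="concordkit"):
            out = ck.resolve_probe_map(table, seed=0, genes=["g1", "g2"])
        assert "g2" not in out.index
        assert any("g2" in rec.message for rec in caplog.records)


class TestGeneCorrelation:
    def test_exact_agreement_and_inversion(self):
        samples = ["s0", "s1", "s2"]
        nc = ck.ExpressionMatrix(pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0]}, index=samples).T)
        array_same = ck.ExpressionMatrix(pd.DataFrame(
            {"ps1": [1.0, 2.0, 3.0]}, index=samples).T)
        array_neg = ck.ExpressionMatrix(pd.DataFrame(
            {"ps1": [-1.0, -2.0, -3.0]}, index=samples).T)
        mapping = pd.Series({"g1": "ps1"})
        assert ck.gene_correlation(array_same, nc, mapping) \
            .at["g1", "pearson_r"] == pytest.approx(1.0)
        assert ck.gene_correlation(array_neg, nc, mapping) \
            .at["g1", "pearson_r"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        samples = ["s0", "s1", "s2"]
        nc = ck.ExpressionMatrix(pd.DataFrame(
            {"g1": [1.0, 2.0, 4.0]}, index=samples).T)
        arr = ck.ExpressionMatrix(pd.DataFrame(
            {"ps1": [1.0, 2.0, 3.0]}, index=samples).T)
        r = ck.gene_correlation(arr, nc, pd.Series({"g1": "ps1"})) \
            .at["g1", "pearson_r"]
        assert r == pytest.approx(9 / np.sqrt(84), abs=1e-4)

    def test_zero_variance_reported_not_dropped(self):
        samples = ["s0", "s1", "s2"]
        nc = ck.ExpressionMatrix(pd.DataFrame(
            {"g1": [2.0, 2.0, 2.0]}, index=samples).T)
        arr = ck.ExpressionMatrix(pd.DataFrame(
            {"ps1": [1.0, 2.0, 3.0]}, index=samples).T)
        out = ck.gene_correlation(arr, nc, pd.Series({"g1": "ps1"}))
        assert np.isnan(out.at["g1", "pearson_r"])
        assert out.at["g1", "reason"] == "zero variance"


class TestSignalDetectionSlope:
    def test_identity_and_scaled_relations(self):
        nc = np.array([3.0, 5.0, 9.0, 11.0])
        assert ck.signal_detection_slope(nc, nc)[0] == pytest.approx(1.0)
        slope, intercept = ck.signal_detection_slope(0.5 * nc + 7, nc)
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(7.0)

    def test_hand_ols(self):
        slope, _ = ck.signal_detection_slope([1.0, 2.0, 2.0], [0.0, 1.0, 2.0])
        assert slope == pytest.approx(0.5)

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(ck.PipelineError, match="zero predictor"):
            ck.signal_detection_slope([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPairwiseLogratioSd:
    @pytest.mark.parametrize("vals,expected", [
        ([3.0, 3.0, 3.0], 0.0),
        ([0.0, 2.0], 2.0),                 # differences {+2, -2}
        ([1.0, 2.0, 3.0], np.sqrt(2.0)),   # sqrt(2) * sample SD with s = 1
    ])
    def test_enumerated_examples(self, vals, expected):
        assert ck.pairwise_logratio_sd(vals) == pytest.approx(expected)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    def test_equals_sqrt2_times_sample_sd(self, vals):
        x = np.asarray(vals)
        expected = np.sqrt(2.0) * x.std(ddof=1)
        assert ck.pairwise_logratio_sd(x) == pytest.approx(expected, abs=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ck.PipelineError):
            ck.pairwise_logratio_sd([1.0])


class TestNoiseGeneSets:
    def _inputs(self, nc_vals, array_vals, expressed):
        samples = [f"s{j}" for j in range(len(next(iter(nc_vals.values()))))]
        nc = ck.ExpressionMatrix(pd.DataFrame(nc_vals, index=samples).T)
        arr = ck.ExpressionMatrix(pd.DataFrame(array_vals, index=samples).T)
        calls = ck.ExpressionCalls(threshold=1.0,
                                   expressed=pd.Series(expressed))
        return calls, nc, arr

    def test_invariant_set_membership(self):
        calls, nc, arr = self._inputs(
            {"g1": [5.0, 5.1, 5.0, 5.1]}, {"g1": [10.0, 10.1, 10.0, 10.1]},
            {"g1": True})
        unexpr, invar = ck.noise_gene_sets(calls, nc, arr, CFG)
        assert invar == ["g1"] and unexpr == []

    def test_saturated_gene_excluded(self):
        calls, nc, arr = self._inputs(
            {"g1": [5.0, 5.1, 5.0, 5.1]}, {"g1": [11.5, 11.6, 11.5, 11.4]},
            {"g1": True})
        assert ck.noise_gene_sets(calls, nc, arr, CFG) == ([], [])

    def test_unexpressed_gene_only_in_unexpressed_set(self):
        calls, nc, arr = self._inputs(
            {"g1": [0.0, 0.1, 0.0, 0.1]}, {"g1": [12.0, 12.0, 12.0, 12.0]},
            {"g1": False})
        unexpr, invar = ck.noise_gene_sets(calls, nc, arr, CFG)
        assert unexpr == ["g1"] and invar == []


class TestMannWhitney:
    def test_identical_multisets_give_central_u(self):
        a = [1.0, 2.0, 3.0]
        u, _ = ck.mann_whitney(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)

    def test_exact_enumeration_of_small_separated_samples(self):
        u, p = ck.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, abs=1e-12)

    def test_exact_and_normal_agree_on_moderate_samples(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 15)
        _, p_exact = ck.mann_whitney(a, b, method="exact")
        _, p_norm = ck.mann_whitney(a, b, method="normal")
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ck.DataValidationError):
            ck.mann_whitney([], [1.0])


class TestConcordanceTable:
    def _identical_platform_inputs(self, n_genes=5, n_samples=6, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{j}" for j in range(n_samples)]
        genes = [f"g{i}" for i in range(n_genes)]
        vals = rng.normal(8, 1, size=(n_genes, n_samples))
        nc = ck.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        arr = ck.ExpressionMatrix(pd.DataFrame(
            vals, index=[f"ps_{g}" for g in genes], columns=samples))
        calls = ck.ExpressionCalls(threshold=1.0,
                                   expressed=pd.Series(True, index=genes))
        mapping = pd.Series({g: f"ps_{g}" for g in genes})
        return arr, nc, calls, mapping

    def test_identical_platforms_give_unit_slope_and_correlation(self):
        arr, nc, calls, mapping = self._identical_platform_inputs()
        table, _ = ck.concordance_table(arr, nc, calls, mapping, CFG)
        np.testing.assert_allclose(table["pearson_r"], 1.0)
        np.testing.assert_allclose(table["slope"], 1.0, atol=1e-9)
        assert table["passes_r_filter"].all()

    def test_boundary_correlation_fails_strict_filter(self):
        arr, nc, calls, mapping = self._identical_platform_inputs(n_genes=1)
        table, _ = ck.concordance_table(arr, nc, calls, mapping, CFG)
        row = table.iloc[0]
        assert row["passes_r_filter"]  # r = 1 > 0.5
        cfg_strict = ck.AnalysisConfig(correlation_min=1.0)
        table2, _ = ck.concordance_table(arr, nc, calls, mapping, cfg_strict)
        assert not table2.iloc[0]["passes_r_filter"]  # r == threshold -> fail

    def test_slope_equals_r_times_sd_ratio(self, default_run):
        """OLS identity slope = r * SD_array / SD_nc on pipeline output."""
        for res in default_run["results"].values():
            table = res.concordance.dropna(subset=["slope"])
            expected = table["pearson_r"] * np.sqrt(
                table["array_variance"] / table["nc_variance"])
            np.testing.assert_allclose(table["slope"], expected, atol=1e-9)


def test_noise_ordering_matches_generative_sds(default_run):
    """Quieter arms yield lower unexpressed-gene log-ratio SD distributions."""
    summaries = {ct: res.noise for ct, res in default_run["results"].items()}
    cmp = ck.compare_noise(summaries)
    row = cmp[(cmp["gene_set"] == "unexpressed")
              & (cmp["cell_type_a"] == "CD14") & (cmp["cell_type_b"] == "CD4")]
    assert row["median_sd_a"].iloc[0] > row["median_sd_b"].iloc[0]
    assert row["p_value"].iloc[0] < 0.05
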