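"""Normalization, DE screening, Z-scoring, and relative quantification."""

import numpy as np
import pandas as pd
import pytest

from cerna_forge.de import (DEThresholds, binomial_exact_test, ddct, de_screen,
                            estimate_common_dispersion, expression_tier, fpkm,
                            nb_exact_test, summarize_de, zscore_rows)
from cerna_forge.matrix import ExpressionMatrix, SampleDesign
from cerna_forge.synthetic import GeneratorConfig, generate_dataset


class TestFPKM:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s": [10, 0, 250]}, index=["a", "b", "c"])
        lengths = pd.Series({"a": 1000, "b": 500, "c": 2500})
        totals = pd.Series({"s": 1e6})
        out = fpkm(counts, lengths, totals)
        assert out.loc["a", "s"] == pytest.approx(10.0)
        assert out.loc["b", "s"] == 0.0
        out2 = fpkm(pd.DataFrame({"s": [250]}, index=["c"]),
                    pd.Series({"c": 2500}), pd.Series({"s": 2e7}))
        assert out2.loc["c", "s"] == pytest.approx(5.0, abs=1e-12)

    def test_zero_length_names_feature(self):
        with pytest.raises(ValueError, match="bad"):
            fpkm(pd.DataFrame({"s": [1]}, index=["bad"]),
                 pd.Series({"bad": 0}), pd.Series({"s": 1e6}))

    def test_tier_annotation(self):
        vals = pd.DataFrame({"s1": [60.0, 10.0], "s2": [80.0, 20.0]}, index=["hi", "lo"])
        tier = expression_tier(vals)
        assert tier["hi"] == "medium_high" and tier["lo"] == "low"


def two_group_matrix(rows, samples=6):
    cols = [f"A{i}-L" for i in range(1, samples // 2 + 1)] + \
           [f"B{i}-L" for i in range(1, samples // 2 + 1)]
    df = pd.DataFrame(rows, columns=cols)
    df.index = [f"f{i}" for i in range(len(df))]
    return ExpressionMatrix(df, "counts")


def design_for(matrix):
    ids = matrix.sample_ids
    return SampleDesign(ids, {s: s[0] for s in ids})


class TestDEScreen:
    def test_identical_groups_are_ns(self):
        m = two_group_matrix([[10, 11, 9, 10, 11, 9], [100, 90, 110, 100, 90, 110]])
        res = de_screen(m, design_for(m), ("A", "B"))
        assert set(res["direction"]) == {"ns"}
        assert res["log2FC"].abs().max() < 0.2

    def test_strong_shift_detected_up(self):
        rows = [[50, 55, 45, 400, 420, 380]] + [[30, 31, 29, 30, 31, 29]] * 10
        m = two_group_matrix(rows)
        res = de_screen(m, design_for(m), ("A", "B"))
        assert res.iloc[0]["direction"] == "up"
        assert res.iloc[0]["log2FC"] > 1

    def test_group_swap_negates_log2fc(self):
        rng = np.random.default_rng(8)
        m = two_group_matrix(rng.integers(5, 500, (20, 6)))
        d = design_for(m)
        ab = de_screen(m, d, ("A", "B"))
        ba = de_screen(m, d, ("B", "A"))
        assert np.allclose(ab["log2FC"], -ba["log2FC"], atol=1e-12)
        assert np.allclose(ab["p_value"], ba["p_value"], atol=1e-9)

    def test_never_reports_small_fold_change(self):
        rng = np.random.default_rng(1)
        m = two_group_matrix(rng.integers(5, 500, (50, 6)))
        res = de_screen(m, design_for(m), ("A", "B"),
                        DEThresholds("p", 0.5, 1.0))
        reported = res[res["direction"] != "ns"]
        assert (reported["log2FC"].abs() > 1.0).all()

    def test_unknown_group_rejected(self):
        m = two_group_matrix([[1, 2, 3, 4, 5, 6]])
        with pytest.raises(ValueError):
            de_screen(m, design_for(m), ("A", "Z"))

    def test_planted_de_recovered(self, dataset):
        results = {}
        for comp in [("A", "B"), ("A", "C"), ("B", "C")]:
            r = de_screen(dataset.gene_expr, dataset.design, comp)
            results[f"{comp[0]}_vs_{comp[1]}"] = r.set_index("feature_id")
        for fid, comp in dataset.truth.de_features.items():
            assert results[comp].loc[fid, "direction"] != "ns"

    def test_null_calibration(self):
        """Fraction of raw p < 0.05 on structure-free data sits near 0.05."""
        cfg = GeneratorConfig(n_genes=1020, n_lncrnas=10, n_circs=10,
                              n_triplets=0, n_de=0, dispersion=0.0)
        ds = generate_dataset(cfg, seed=9)
        res = de_screen(ds.gene_expr, ds.design, ("A", "B"))
        frac = float((res["p_value"] < 0.05).mean())
        n = len(res)
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n)
        assert 0.05 - half_width <= frac <= 0.05 + half_width

    def test_nb_test_reduces_to_binomial_at_zero_dispersion(self):
        c1, c2 = np.array([10, 12, 8]), np.array([30, 28, 35])
        lib1 = lib2 = 3e4
        assert nb_exact_test(c1, c2, lib1, lib2, 0.0) == \
            binomial_exact_test(c1, c2, lib1, lib2)
        # with dispersion, p is larger (overdispersion absorbs signal)
        assert nb_exact_test(c1, c2, lib1, lib2, 0.3) > \
            binomial_exact_test(c1, c2, lib1, lib2)

    def test_dispersion_estimate_nonnegative(self, dataset):
        phi = estimate_common_dispersion(dataset.gene_expr.values, dataset.design)
        assert phi >= 0.0


class TestSummaries:
    def test_aggregation(self):
        res = pd.DataFrame({
            "comparison": ["A_vs_B"] * 3 + ["A_vs_C"],
            "direction": ["up", "down", "ns", "down"],
        })
        out = summarize_de(res).set_index("comparison")
        assert out.loc["A_vs_B"].tolist() == [1, 1, 2]
        assert out.loc["A_vs_C"].tolist() == [0, 1, 1]

    def test_empty(self):
        out = summarize_de(pd.DataFrame(columns=["comparison", "direction"]))
        assert len(out) == 0


class TestZscore:
    def test_simple_row(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]},
                                          index=["f"]), "counts")
        z = zscore_rows(m)
        assert np.allclose(z.values.loc["f"], [-1, 0, 1])

    def test_hand_computed_row(self):
        row = [2, 4, 4, 4, 5, 5, 7, 9.0]
        m = ExpressionMatrix(pd.DataFrame([row], index=["f"],
                                          columns=list("abcdefgh")), "counts")
        z = zscore_rows(m).values.loc["f"].to_numpy()
        sd = np.sqrt(32 / 7)  # mean 5, sample sd ~2.138
        assert np.allclose(z, (np.array(row) - 5) / sd, atol=1e-12)

    def test_rows_standardized(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(pd.DataFrame(rng.integers(1, 100, (30, 9)).astype(float)),
                             "counts")
        z = zscore_rows(m).values
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_constant_row_dropped_with_warning(self):
        m = ExpressionMatrix(pd.DataFrame({"a": [5.0, 1.0], "b": [5.0, 2.0],
                                           "c": [5.0, 3.0]}, index=["flat", "ok"]),
                             "counts")
        with pytest.warns(UserWarning):
            z = zscore_rows(m)
        assert list(z.values.index) == ["ok"]


class TestDDCT:
    @pytest.mark.parametrize("cts,expected", [
        ((20, 20, 20, 20), 1.0),      # ddCt = 0
        ((21, 20, 20, 20), 0.5),      # ddCt = 1
        ((18, 20, 20, 20), 4.0),      # ddCt = -2
    ])
    def test_values(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 20, 20, 20)
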