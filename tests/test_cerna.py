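"""Sponge screening: target intersection, hypergeometric evidence, key tiers,
immune circRNA ranking, and network edge construction."""

import numpy as np
import pandas as pd
import pytest

from cerna_forge.cerna import (TargetMap, build_edges, candidate_pairs,
                               hypergeom_shared, intersect_targets, screen_cerna,
                               screen_immune_circ, select_key, write_sif)
from cerna_forge.matrix import ExpressionMatrix


def tm(name, pairs):
    return TargetMap(name, set(pairs))


class TestIntersect:
    def test_consensus(self):
        out = intersect_targets([
            tm("a", [("m1", "g1"), ("m1", "g2")]),
            tm("b", [("m1", "g1")]),
            tm("c", [("m1", "g1"), ("m1", "g3")]),
        ])
        assert out.pairs == {("m1", "g1")}

    def test_idempotent_and_disjoint(self):
        same = tm("a", [("m1", "g1"), ("m2", "g2")])
        assert intersect_targets([same, same, same]).pairs == same.pairs
        assert intersect_targets([same, tm("b", [("m3", "g3")])]).pairs == set()

    def test_needs_two_maps(self):
        with pytest.raises(ValueError):
            intersect_targets([tm("a", [("m", "g")])])
        with pytest.raises(ValueError):
            intersect_targets([])


class TestHypergeomShared:
    def test_combinatorial_example(self):
        assert hypergeom_shared(K=3, n=3, k=3, N=10) == pytest.approx(1 / 120, rel=1e-12)

    def test_zero_overlap(self):
        assert hypergeom_shared(K=5, n=4, k=0, N=30) == 1.0

    def test_candidate_pairs_fields_consistent(self):
        targets = tm("f", [("m1", "nc1"), ("m2", "nc1"), ("m1", "g1"),
                           ("m3", "g1"), ("m2", "g2")])
        out = candidate_pairs(targets, ["nc1"], ["g1", "g2"])
        assert set(zip(out["ce_a"], out["ce_b"])) == {("nc1", "g1"), ("nc1", "g2")}
        for r in out.itertuples():
            assert r.k <= min(r.K, r.n) <= r.N == 3
            assert 0 < r.hyper_p <= 1


def planted_exprs():
    """Noiseless triplet: miRNA exactly anti-linear to sponge and mRNA."""
    cols = [f"s{i}" for i in range(9)]
    base = np.linspace(1.0, 9.0, 9)
    mir = ExpressionMatrix(pd.DataFrame([10 - base], index=["m1"], columns=cols), "RPM")
    ce = ExpressionMatrix(pd.DataFrame([base, base * 2], index=["nc1", "g1"],
                                       columns=cols), "RPM")
    return mir, ce


class TestScreen:
    def test_planted_pair_retained_in_noiseless_limit(self):
        mir, ce = planted_exprs()
        pairs = pd.DataFrame([{"ce_a": "nc1", "ce_b": "g1", "shared_mirnas": "m1",
                               "k": 3, "K": 3, "n": 3, "N": 30,
                               "hyper_p": hypergeom_shared(3, 3, 3, 30)}])
        out = screen_cerna(pairs, mir, ce)
        assert list(out["ce_a"]) == ["nc1"]
        assert out.iloc[0]["r_ab"] == pytest.approx(1.0)

    def test_nonsignificant_hypergeom_dropped(self):
        mir, ce = planted_exprs()
        pairs = pd.DataFrame([{"ce_a": "nc1", "ce_b": "g1", "shared_mirnas": "m1",
                               "k": 1, "K": 3, "n": 3, "N": 30, "hyper_p": 0.2}])
        assert len(screen_cerna(pairs, mir, ce)) == 0

    def test_positive_mirna_correlation_blocks(self):
        mir, ce = planted_exprs()
        pos_mir = ExpressionMatrix(mir.values * -1 + 20, "RPM")  # now correlates +
        pairs = pd.DataFrame([{"ce_a": "nc1", "ce_b": "g1", "shared_mirnas": "m1",
                               "k": 3, "K": 3, "n": 3, "N": 30, "hyper_p": 1e-4}])
        assert len(screen_cerna(pairs, pos_mir, ce)) == 0

    def test_anti_monotone_in_alpha(self, dataset):
        final = intersect_targets(dataset.target_maps)
        nc = [t.transcript_id for t in dataset.lnc_transcripts] + \
             list(dataset.circ_expr.values.index)
        mrna = [f for f in dataset.gene_expr.feature_ids if f.startswith("gene_")]
        cands = candidate_pairs(final, nc, mrna)
        loose = screen_cerna(cands, dataset.mirna_expr, dataset.gene_expr,
                             dataset.circ_expr, alpha=0.05)
        tight = screen_cerna(cands, dataset.mirna_expr, dataset.gene_expr,
                             dataset.circ_expr, alpha=0.005)
        assert set(zip(tight["ce_a"], tight["ce_b"])) <= set(zip(loose["ce_a"], loose["ce_b"]))

    def test_missing_expression_skipped(self):
        mir, ce = planted_exprs()
        pairs = pd.DataFrame([{"ce_a": "ghost", "ce_b": "g1", "shared_mirnas": "m1",
                               "k": 3, "K": 3, "n": 3, "N": 30, "hyper_p": 1e-4}])
        assert len(screen_cerna(pairs, mir, ce)) == 0


class TestSelectKey:
    def test_tiers(self):
        recs = pd.DataFrame({"id": ["a", "b", "c", "d"],
                             "r": [-0.95, -0.9, -0.7, -0.63],
                             "p": [0.001, 0.001, 0.01, 0.2]})
        out = select_key(recs)
        assert out.set_index("id")["is_key"].tolist() == [True, False, False, False]
        assert out.set_index("id")["is_significant"].tolist() == [True, True, True, False]


class TestImmuneCirc:
    def _inputs(self):
        circ = pd.DataFrame({
            "circ_id": [f"c{i:02d}" for i in range(12)],
            "host_gene": [f"g{i:02d}" for i in range(12)],
        })
        enr = pd.DataFrame({"term_id": ["t_imm", "t_met"], "significant": [True, True]})
        classes = {"t_imm": "Immune system", "t_met": "Metabolism"}
        term_genes = {"t_imm": {f"g{i:02d}" for i in range(12)}, "t_met": {"g00"}}
        vals = pd.DataFrame({"s1": np.arange(12.0)}, index=circ["circ_id"])
        expr = ExpressionMatrix(vals, "RPM")
        return circ, enr, classes, term_genes, expr

    def test_top_10_by_expression(self):
        circ, enr, classes, term_genes, expr = self._inputs()
        out = screen_immune_circ(circ, enr, classes, expr, term_genes, top_n=10)
        assert len(out) == 10
        assert out.iloc[0]["circ_id"] == "c11"  # highest mean expression first
        assert "c00" not in set(out["circ_id"]) and "c01" not in set(out["circ_id"])

    def test_tie_broken_lexicographically(self):
        circ, enr, classes, term_genes, expr = self._inputs()
        expr.values[:] = 1.0
        out = screen_immune_circ(circ, enr, classes, expr, term_genes, top_n=3)
        assert list(out["circ_id"]) == ["c00", "c01", "c02"]

    def test_no_significant_immune_pathway(self):
        circ, enr, classes, term_genes, expr = self._inputs()
        enr.loc[enr["term_id"] == "t_imm", "significant"] = False
        out = screen_immune_circ(circ, enr, classes, expr, term_genes)
        assert len(out) == 0


class TestEdges:
    def _exprs(self):
        cols = [f"s{i}" for i in range(9)]
        base = np.linspace(1.0, 9.0, 9)
        rng = np.random.default_rng(0)
        mir = ExpressionMatrix(pd.DataFrame(
            [10 - base, np.abs(10 - base + 4.0 * rng.normal(size=9) + 3)],
            index=["m1", "m2"], columns=cols), "RPM")
        ce = ExpressionMatrix(pd.DataFrame([base], index=["g1"], columns=cols), "RPM")
        return mir, ce

    def test_threshold_and_self_loops(self):
        mir, ce = self._exprs()
        targets = tm("f", [("m1", "g1"), ("m2", "g1"), ("g1", "g1")])
        pairs = pd.DataFrame(columns=["ce_a", "ce_b", "hyper_p"])
        edges = build_edges(pairs, targets, mir, ce, r_cut=-0.95)
        # m1 is exactly anti-linear (r = -1); m2 is noisy and misses -0.95
        assert ("m1", "g1") in set(zip(edges["source"], edges["target"]))
        assert ("m2", "g1") not in set(zip(edges["source"], edges["target"]))
        assert not (edges["source"] == edges["target"]).any()

    def test_cerna_edges_appended_and_sorted(self, tmp_path):
        mir, ce = self._exprs()
        targets = tm("f", [("m1", "g1")])
        pairs = pd.DataFrame([{"ce_a": "nc1", "ce_b": "g1", "hyper_p": 0.01,
                               "r_ab": 0.99}])
        edges = build_edges(pairs, targets, mir, ce)
        assert "ceRNA" in set(edges["edge_type"])
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
        write_sif(edges, p1)
        write_sif(edges, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert b"\t" in p1.read_bytes()
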