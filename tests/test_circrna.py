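"""Back-splice candidate filtering, RPM arithmetic, and circRNA typing."""

import numpy as np
import pandas as pd
import pytest

from cerna_forge.annotation import read_gtf
from cerna_forge.circrna import (FILTER_CONDITIONS, classify_all, classify_circ,
                                 evaluate_conditions, filter_candidates,
                                 rpm_normalize)
from cerna_forge.synthetic import generate_circ_candidates


def make_candidate(**over):
    base = dict(chrom="chr1", start=1000, end=1349, strand="+", breakpoints=1,
                anchor_overlap=2, edit=2, n_uniq=5, best_qual_A=36, best_qual_B=0)
    base.update(over)
    return pd.DataFrame([base])


def brute_force_pass(row, n_samples):
    """Independent condition enumerator (no shared code with the filter)."""
    return (row["breakpoints"] == 1 and row["anchor_overlap"] <= 2
            and row["edit"] <= 2 and row["n_uniq"] > 2
            and (row["best_qual_A"] > 35 or row["best_qual_B"] > 35)
            and row["n_uniq"] > n_samples // 2
            and (row["end"] - row["start"] + 1) < 100_000)


class TestFilter:
    def test_boundary_candidate_retained(self):
        kept = filter_candidates(make_candidate(), n_samples=9)
        assert len(kept) == 1  # floor(9/2)=4 < 5

    def test_nuniq_at_half_rejected_with_reason(self):
        checks = evaluate_conditions(make_candidate(n_uniq=4), n_samples=9)
        assert not checks["pass_all"].iloc[0]
        assert checks["fail_reason"].iloc[0] == "n_uniq>samples/2"

    def test_span_at_100k_rejected(self):
        cand = make_candidate(end=1000 + 100_000 - 1)  # span exactly 100 kb
        checks = evaluate_conditions(cand, n_samples=9)
        assert checks["fail_reason"].iloc[0] == "length"
        # one below the limit passes
        assert len(filter_candidates(make_candidate(end=1000 + 100_000 - 2), 9)) == 1

    def test_quality_is_a_disjunction(self):
        assert len(filter_candidates(make_candidate(best_qual_A=0, best_qual_B=36), 9)) == 1
        assert len(filter_candidates(make_candidate(best_qual_A=35, best_qual_B=35), 9)) == 0

    def test_missing_column_named(self):
        with pytest.raises(KeyError, match="edit"):
            filter_candidates(make_candidate().drop(columns=["edit"]), 9)

    def test_recovers_constructed_truth(self):
        cand = generate_circ_candidates(n_pass=12, n_fail=14, seed=5)
        kept = filter_candidates(cand, n_samples=9)
        assert list(kept.index) == list(cand.index[cand["planted_pass"]])

    def test_empty_pass_set(self):
        cand = generate_circ_candidates(n_pass=0, n_fail=5, seed=2)
        assert len(filter_candidates(cand, 9)) == 0

    def test_all_conditions_covered_and_labeled(self):
        cand = generate_circ_candidates(n_pass=3, n_fail=7, seed=3)
        failing = cand[~cand["planted_pass"]]
        assert set(failing["violated"]) == set(FILTER_CONDITIONS)
        checks = evaluate_conditions(cand, n_samples=9)
        assert list(checks.loc[failing.index, "fail_reason"]) == list(failing["violated"])

    def test_retained_pass_bruteforce_recheck(self):
        cand = generate_circ_candidates(n_pass=20, n_fail=20, seed=7)
        kept = filter_candidates(cand, n_samples=9)
        for _, row in kept.iterrows():
            assert brute_force_pass(row, 9)
        rejected = cand.loc[~cand.index.isin(kept.index)]
        for _, row in rejected.iterrows():
            assert not brute_force_pass(row, 9)


class TestRPM:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [5, 0, 7]}, index=["a", "b", "c"])
        totals = pd.Series({"s1": 1e6})
        out = rpm_normalize(counts, totals)
        assert out.loc["a", "s1"] == 5.0 and out.loc["b", "s1"] == 0.0
        out2 = rpm_normalize(pd.DataFrame({"s": [7]}), pd.Series({"s": 2.5e6}))
        assert out2.iloc[0, 0] == pytest.approx(2.8, abs=1e-12)

    def test_round_trip_conservation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (20, 9)).astype(float),
                              columns=[f"s{i}" for i in range(9)])
        totals = pd.Series(rng.uniform(1e6, 3e7, 9), index=counts.columns)
        rpm = rpm_normalize(counts, totals)
        back = rpm.mul(totals, axis=1) / 1e6
        assert np.allclose(back.to_numpy(), counts.to_numpy(), atol=1e-9)

    def test_zero_total_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            rpm_normalize(pd.DataFrame({"s1": [1]}), pd.Series({"s1": 0.0}))


class TestClassify:
    def test_forced_types_on_tiny_annotation(self, tiny_gtf):
        ann = read_gtf(tiny_gtf)
        # gA: exons (internal 0-based) [1000,2000) [5000,6000) [9000,10000)
        assert classify_circ("chr1", 1000, 6000, "+", ann) == ("annot_exons", "gA")
        assert classify_circ("chr1", 1100, 1900, "+", ann) == ("one_exon", "gA")
        assert classify_circ("chr1", 1500, 3000, "+", ann) == ("exon_intron", "gA")
        assert classify_circ("chr1", 2500, 3500, "+", ann) == ("intronic", "gA")
        assert classify_circ("chr1", 1200, 1800, "-", ann) == ("antisense", "gA")
        assert classify_circ("chr1", 20000, 20400, "+", ann) == ("intergenic", None)

    def test_unknown_chromosome_is_intergenic(self, tiny_gtf):
        ann = read_gtf(tiny_gtf)
        assert classify_circ("chrZ", 10, 500, "+", ann) == ("intergenic", None)

    def test_types_partition_dataset(self, dataset):
        kept = filter_candidates(dataset.circ_candidates, 9)
        recs = classify_all(kept, dataset.annotation)
        counts = recs["circ_type"].value_counts()
        assert counts.sum() == len(recs)
        assert (recs["host_gene"] == "").equals(recs["circ_type"] == "intergenic")

    def test_recovers_planted_types(self, dataset):
        kept = filter_candidates(dataset.circ_candidates, 9)
        recs = classify_all(kept, dataset.annotation)
        for r in recs.itertuples():
            assert dataset.truth.true_classes[r.circ_id] == r.circ_type
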