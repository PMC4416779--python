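import numpy as np
import pandas as pd
import pytest

from synlethal.io_formats import CNVMatrix, ExpressionStatusMatrix, GeneAnnotation, LabeledPairSet
from synlethal.pair_features import (
    EVENTS,
    FeatureConfig,
    build_feature_table,
    coloss_fraction,
    exclude_same_chromosome,
    flag_high_deletion_samples,
    single_loss_rate,
    updown_fraction,
)
from conftest import random_status_matrix


# Independent oracle: literal per-sample recount of the event definitions,
# written from the status-set tables rather than the EventSpec machinery.
def brute_force_fraction(a_vals, b_vals, name):
    numer = {
        "homCL": {(-2, -2)},
        "hetCL": {(-1, -1)},
        "mixCL": {(-2, -1), (-1, -2)},
        "co_under": {(-1, -1)},
        "expr_updown": {(-1, 1), (1, -1)},
        "cnv_updown": {(u, d) for u in (1, 2) for d in (-1, -2)}
               | {(d, u) for u in (1, 2) for d in (-1, -2)},
    }[name]
    denom = {
        "homCL": {(-2, 0), (0, -2), (-2, -2)},
        "hetCL": {(-1, 0), (0, -1), (-1, -1)},
        "mixCL": {(-2, 0), (0, -2), (-2, -1), (-1, -2)},
        "co_under": {(-1, 0), (0, -1), (-1, -1)},
        "expr_updown": {(-1, -1), (-1, 0), (0, -1), (-1, 1), (1, -1)},
        "cnv_updown": {(a, b) for a in (-2, -1, 0, 1, 2) for b in (-2, -1, 0, 1, 2)
                       if a in (-2, -1) or b in (-2, -1)},
    }[name]
    n_event = sum((a, b) in numer for a, b in zip(a_vals, b_vals))
    n_t = sum((a, b) in denom for a, b in zip(a_vals, b_vals))
    return n_event, n_t, (n_event / n_t if n_t else float("nan"))


class TestHighDeletionFilter:
    def test_strictly_greater_than_threshold(self):
        status = np.zeros((5, 3), dtype=int)
        status[:3, 0] = -2  # 3 hom-deleted genes in sample s0
        status[:2, 1] = -2  # 2 in s1
        m = CNVMatrix([f"g{i}" for i in range(5)], ["s0", "s1", "s2"], status)
        assert flag_high_deletion_samples(m, threshold=2) == {"s0"}
        assert flag_high_deletion_samples(m, threshold=3) == set()

    def test_no_deletions_empty(self):
        m = CNVMatrix(["A", "B"], ["s0", "s1"], np.zeros((2, 2), dtype=int))
        assert flag_high_deletion_samples(m, threshold=0) == set()


class TestFractionCounts:
    def test_homcl_example(self, tiny_cnv):
        # statuses (-2,-2),(-2,0),(-2,0),(0,-2),(0,0),(-1,0),(1,2),(0,-2)
        n_event, n_t, f = coloss_fraction(("A", "B"), tiny_cnv, "homCL")
        assert (n_event, n_t, f) == (1, 5, 0.2)

    def test_homcl_with_excluded_sample(self, tiny_cnv):
        n_event, n_t, f = coloss_fraction(("A", "B"), tiny_cnv, "homCL",
                                          excluded_samples={"s0"})
        assert (n_event, n_t, f) == (0, 4, 0.0)

    def test_empty_denominator_missing(self):
        m = CNVMatrix(["A", "B"], ["s0", "s1"], np.zeros((2, 2), dtype=int))
        n_event, n_t, f = coloss_fraction(("A", "B"), m, "homCL")
        assert n_t == 0 and np.isnan(f)

    def test_updown_example(self):
        status = np.array([[-1, 1, -1, -1, 0, 0],
                           [1, -1, 0, -1, 0, -1]])
        m = ExpressionStatusMatrix(["A", "B"], [f"s{i}" for i in range(6)], status)
        n_event, n_t, f = updown_fraction(("A", "B"), m, "expression")
        assert (n_event, n_t, f) == (2, 5, 0.4)

    def test_updown_bounds(self):
        all_updown = ExpressionStatusMatrix(
            ["A", "B"], ["s0", "s1"], np.array([[-1, -1], [1, 1]]))
        assert updown_fraction(("A", "B"), all_updown, "expression")[2] == 1.0
        no_under = ExpressionStatusMatrix(
            ["A", "B"], ["s0"], np.array([[0], [1]]))
        assert np.isnan(updown_fraction(("A", "B"), no_under, "expression")[2])

    def test_absent_gene_named(self, tiny_cnv):
        with pytest.raises(KeyError, match="Z"):
            coloss_fraction(("A", "Z"), tiny_cnv, "homCL")

    @pytest.mark.parametrize("event", ["homCL", "hetCL", "mixCL", "cnv_updown"])
    def test_oracle_equivalence_cnv(self, event):
        rng = np.random.default_rng(42)
        for _ in range(50):
            genes, samples, status = random_status_matrix(rng, [-2, -1, 0, 1, 2])
            m = CNVMatrix(genes, samples, status)
            a, b = rng.choice(len(genes), size=2, replace=False)
            got = coloss_fraction((genes[a], genes[b]), m, event)
            want = brute_force_fraction(status[a], status[b], event)
            assert got[:2] == want[:2]
            np.testing.assert_equal(got[2], want[2])

    @pytest.mark.parametrize("event", ["co_under", "expr_updown"])
    def test_oracle_equivalence_expression(self, event):
        rng = np.random.default_rng(43)
        for _ in range(50):
            genes, samples, status = random_status_matrix(rng, [-1, 0, 1])
            m = ExpressionStatusMatrix(genes, samples, status)
            a, b = rng.choice(len(genes), size=2, replace=False)
            got = coloss_fraction((genes[a], genes[b]), m, event)
            want = brute_force_fraction(status[a], status[b], event)
            assert got[:2] == want[:2]
            np.testing.assert_equal(got[2], want[2])

    def test_symmetry_under_gene_swap(self):
        rng = np.random.default_rng(44)
        genes, samples, status = random_status_matrix(rng, [-2, -1, 0, 1, 2], 4, 40)
        m = CNVMatrix(genes, samples, status)
        for event in ("homCL", "hetCL", "mixCL", "cnv_updown"):
            assert (coloss_fraction((genes[0], genes[1]), m, event)
                    == coloss_fraction((genes[1], genes[0]), m, event))

    def test_neutral_samples_do_not_change_fractions(self):
        # appending (0,0) samples touches no numerator and (for these events)
        # no denominator cell
        rng = np.random.default_rng(45)
        genes, samples, status = random_status_matrix(rng, [-2, -1, 0, 1, 2], 2, 20)
        padded = np.concatenate([status, np.zeros((2, 10), dtype=status.dtype)], axis=1)
        m1 = CNVMatrix(genes, samples, status)
        m2 = CNVMatrix(genes, samples + [f"z{i}" for i in range(10)], padded)
        for event in ("homCL", "hetCL", "mixCL", "cnv_updown"):
            assert (coloss_fraction((genes[0], genes[1]), m1, event)
                    == coloss_fraction((genes[0], genes[1]), m2, event))

    def test_removing_numerator_sample_weakly_decreases(self, tiny_cnv):
        base = coloss_fraction(("A", "B"), tiny_cnv, "homCL")[2]
        without_numer = coloss_fraction(("A", "B"), tiny_cnv, "homCL",
                                        excluded_samples={"s0"})[2]
        without_denom_only = coloss_fraction(("A", "B"), tiny_cnv, "homCL",
                                             excluded_samples={"s1"})[2]
        assert without_numer <= base <= without_denom_only


class TestSingleLossRate:
    def test_basic_rate(self, tiny_cnv):
        assert single_loss_rate("A", tiny_cnv, -2) == pytest.approx(3 / 8)

    def test_all_match(self):
        m = CNVMatrix(["A"], ["s0", "s1"], np.array([[1, 1]]))
        assert single_loss_rate("A", m, 1) == 1.0

    def test_all_excluded_missing(self, tiny_cnv):
        rate = single_loss_rate("A", tiny_cnv, -2,
                                excluded_samples=set(tiny_cnv.sample_ids))
        assert np.isnan(rate)


class TestChromosomeFilter:
    def test_same_chromosome_dropped(self):
        ann = GeneAnnotation({"G1": "1", "G2": "2", "G3": "1", "G4": "1"})
        out = exclude_same_chromosome([("G1", "G2"), ("G3", "G4")], ann)
        assert out == [("G1", "G2")]

    def test_unannotated_dropped(self):
        ann = GeneAnnotation({"G1": "1", "G2": "2"})
        assert exclude_same_chromosome([("G1", "G5")], ann) == []

    def test_labeled_pair_set_filtering(self):
        ann = GeneAnnotation({"A": "1", "B": "2", "C": "1", "D": "1"})
        ps = LabeledPairSet(pd.DataFrame({
            "gene_a": ["A", "C"], "gene_b": ["B", "D"],
            "label": ["SL", "nonSL"]}))
        out = exclude_same_chromosome(ps, ann)
        assert len(out) == 1
        assert out.pairs.iloc[0]["gene_a"] == "A"

    def test_empty_input(self):
        assert exclude_same_chromosome([], GeneAnnotation({})) == []


class TestFeatureTable:
    def test_composed_fractions(self, tiny_cnv):
        expr = ExpressionStatusMatrix(
            ["A", "B"], [f"s{i}" for i in range(6)],
            np.array([[-1, 1, -1, -1, 0, 0], [1, -1, 0, -1, 0, -1]]))
        ft = build_feature_table([("A", "B")], tiny_cnv, expr,
                                 FeatureConfig(high_deletion_threshold=100))
        row = ft.iloc[0]
        assert row["f1"] == pytest.approx(0.2)
        assert row["f5"] == pytest.approx(0.4)

    def test_f1_respects_deletion_filter(self, tiny_cnv):
        # s0 carries 2 hom-deletions; threshold 1 excludes it from f1 only
        ft = build_feature_table([("A", "B")], tiny_cnv,
                                 ExpressionStatusMatrix(["A", "B"], ["x"],
                                                        np.zeros((2, 1), dtype=int)),
                                 FeatureConfig(high_deletion_threshold=1))
        assert ft.iloc[0]["f1"] == 0.0  # (−2,−2) sample excluded
        assert ft.iloc[0]["nt_homCL"] == 4

    def test_missing_mask_and_duplicates(self):
        cnv = CNVMatrix(["A", "B"], ["s0"], np.zeros((2, 1), dtype=int))
        expr = ExpressionStatusMatrix(["A", "B"], ["s0"], np.zeros((2, 1), dtype=int))
        ft = build_feature_table([("A", "B"), ("B", "A")], cnv, expr)
        assert len(ft) == 1
        assert ft[["f1", "f2", "f3", "f4", "f5"]].isna().all().all()

    def test_pair_with_absent_gene_dropped(self, tiny_cnv):
        expr = ExpressionStatusMatrix(["A", "B"], ["x"], np.zeros((2, 1), dtype=int))
        ft = build_feature_table([("A", "Q")], tiny_cnv, expr)
        assert len(ft) == 0
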