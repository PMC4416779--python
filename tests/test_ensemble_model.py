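import numpy as np
import pandas as pd
import pytest

from synlethal.io_formats import GeneAnnotation, LabeledPairSet
from synlethal.ensemble_model import (
    CVResult,
    EnsembleConfig,
    cross_validate,
    different_chromosome_pairs,
    ensemble_predict,
    precision_recall_points,
    predict_genome_wide,
    roc_auc,
    select_threshold,
    train_ensemble,
    undersample_negatives,
)
from sklearn.linear_model import LogisticRegression


def pair_set(n_pos, n_neg):
    rows = [(f"P{i:03d}a", f"P{i:03d}b", "SL") for i in range(n_pos)]
    rows += [(f"N{i:03d}a", f"N{i:03d}b", "nonSL") for i in range(n_neg)]
    return LabeledPairSet(pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]))


def separable_features(labels, noise=0.0, seed=0):
    """SL rows: f5 high, f1-f4 low; non-SL rows inverted."""
    rng = np.random.default_rng(seed)
    df = labels.pairs.copy()
    is_sl = (df["label"] == "SL").to_numpy()
    for col in ("f1", "f2", "f3", "f4"):
        df[col] = np.where(is_sl, 0.0, 1.0) + noise * rng.normal(size=len(df))
    df["f5"] = np.where(is_sl, 1.0, 0.0) + noise * rng.normal(size=len(df))
    return df[["gene_a", "gene_b", "f1", "f2", "f3", "f4", "f5"]]


class TestUndersampling:
    def test_balances_to_positive_count(self):
        labels = pair_set(3, 10)
        out = undersample_negatives(labels, seed=1)
        assert out.n_positive == 3 and out.n_negative == 3

    def test_already_balanced_unchanged(self):
        labels = pair_set(5, 5)
        out = undersample_negatives(labels, seed=1)
        assert out.n_positive == 5 and out.n_negative == 5

    def test_deterministic_given_seed(self):
        labels = pair_set(4, 30)
        a = undersample_negatives(labels, seed=7)
        b = undersample_negatives(labels, seed=7)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_fewer_negatives_keeps_all(self):
        labels = pair_set(6, 3)
        out = undersample_negatives(labels, seed=0)
        assert out.n_negative == 3


class TestTrainPredict:
    def test_separable_set_learned(self):
        labels = pair_set(10, 40)
        feats = separable_features(labels)
        cfg = EnsembleConfig(n_undersample_replicates=2, n_estimators=10)
        model = train_ensemble(feats, labels, cfg, seed=0)
        preds = model.predict_proba(feats)
        is_sl = (labels.pairs["label"] == "SL").to_numpy()
        assert (preds[is_sl] > 0.5).all()
        assert preds.min() >= 0 and preds.max() <= 1

    def test_single_learner_ensemble(self):
        labels = pair_set(10, 20)
        feats = separable_features(labels, noise=0.05)
        cfg = EnsembleConfig(
            n_undersample_replicates=1,
            base_learners=[("logistic", LogisticRegression(max_iter=500))])
        model = train_ensemble(feats, labels, cfg, seed=0)
        assert model.n_learners == 1
        assert model.predict_proba(feats).shape == (30,)

    def test_identical_rows_give_class_prior(self):
        # balanced training forces probabilities toward the 0.5 prior
        labels = pair_set(10, 10)
        feats = labels.pairs.copy()
        for col in ("f1", "f2", "f3", "f4", "f5"):
            feats[col] = 0.3
        cfg = EnsembleConfig(n_undersample_replicates=1, n_estimators=10)
        model = train_ensemble(feats, labels, cfg, seed=0)
        p = model.predict_proba(feats[["gene_a", "gene_b", "f1", "f2", "f3", "f4", "f5"]])
        assert np.allclose(p, 0.5, atol=0.05)

    def test_mean_rule_is_arithmetic_mean(self):
        labels = pair_set(8, 16)
        feats = separable_features(labels, noise=0.2)
        cfg = EnsembleConfig(n_undersample_replicates=2, n_estimators=10)
        model = train_ensemble(feats, labels, cfg, seed=3)
        X = model._impute(feats)
        manual = np.mean(
            [est.predict_proba(X)[:, list(est.classes_).index(1)]
             for reps in model.replicates for _, est in reps], axis=0)
        np.testing.assert_allclose(model.predict_proba(feats), manual, rtol=1e-12)

    def test_unknown_feature_column_errors(self):
        labels = pair_set(5, 10)
        feats = separable_features(labels)
        model = train_ensemble(feats, labels,
                               EnsembleConfig(n_undersample_replicates=1,
                                              n_estimators=5), seed=0)
        with pytest.raises(KeyError, match="f3"):
            model.predict_proba(feats.drop(columns=["f3"]))

    def test_empty_feature_table_empty_predictions(self):
        labels = pair_set(5, 10)
        feats = separable_features(labels)
        model = train_ensemble(feats, labels,
                               EnsembleConfig(n_undersample_replicates=1,
                                              n_estimators=5), seed=0)
        out = ensemble_predict(model, feats.iloc[:0])
        assert len(out) == 0


class TestMetrics:
    def test_perfect_and_tied_auc(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_derived_value(self):
        # concordant pos-neg pairs: (0.9,0.8) (0.9,0.3) (0.4,0.3) of 4 -> 3/4
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])

    def test_auc_matches_concordant_pair_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(4, 30)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            oracle = np.mean([(p > q) + 0.5 * (p == q)
                              for p in pos for q in neg])
            assert roc_auc(scores, labels) == pytest.approx(oracle)

    def test_pr_points(self):
        pr = precision_recall_points([0.9, 0.8, 0.7], [1, 1, 0])
        at_075 = pr[pr["threshold"] <= 0.8].iloc[0]
        assert at_075["precision"] == 1.0 and at_075["recall"] == 1.0
        top = pr.iloc[0]
        assert top["threshold"] == 0.9
        assert top["precision"] == 1.0 and top["recall"] == pytest.approx(0.5)

    def test_select_threshold(self):
        pr = pd.DataFrame({"threshold": [0.2, 0.6, 0.8],
                           "precision": [0.5, 0.7, 0.9],
                           "recall": [1.0, 0.6, 0.2]})
        thr, prec, rec = select_threshold(pr, 0.67)
        assert (thr, prec, rec) == (0.6, 0.7, 0.6)
        assert select_threshold(pr, 0.0)[0] == 0.2
        with pytest.raises(ValueError, match="0.9"):
            select_threshold(pr, 0.95)


class TestCrossValidation:
    def test_deterministic_and_leak_free(self):
        labels = pair_set(30, 120)
        feats = separable_features(labels, noise=0.3, seed=5)
        cfg = EnsembleConfig(n_undersample_replicates=1, n_estimators=10)
        cv1 = cross_validate(feats, labels, k=5, repeats=2, config=cfg, seed=4)
        cv2 = cross_validate(feats, labels, k=5, repeats=2, config=cfg, seed=4)
        np.testing.assert_array_equal(cv1.repeat_aucs, cv2.repeat_aucs)
        pd.testing.assert_frame_equal(cv1.fold_aucs, cv2.fold_aucs)
        assert cv1.mean_auc > 0.9  # strongly separable
        assert cv1.se_auc >= 0
        assert cv1.mean_tpr.shape == (101,)

    def test_label_permutation_is_chance(self):
        rng = np.random.default_rng(8)
        labels = pair_set(30, 120)
        feats = separable_features(labels, noise=0.3, seed=5)
        permuted = labels.pairs.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        cfg = EnsembleConfig(n_undersample_replicates=1, n_estimators=10)
        cv = cross_validate(feats, LabeledPairSet(permuted), k=5, repeats=2,
                            config=cfg, seed=4)
        assert abs(cv.mean_auc - 0.5) < 0.12

    def test_k_larger_than_class_errors(self):
        labels = pair_set(3, 50)
        feats = separable_features(labels)
        with pytest.raises(ValueError):
            cross_validate(feats, labels, k=5, repeats=1)


class TestGenomeWide:
    def _universe(self):
        # 10 genes on chromosomes of sizes 4/3/3 -> 45 - (6+3+3) = 33 pairs
        genes = [f"g{i}" for i in range(10)]
        chroms = ["1"] * 4 + ["2"] * 3 + ["3"] * 3
        return genes, GeneAnnotation(dict(zip(genes, chroms)))

    def test_pair_universe_count(self):
        genes, ann = self._universe()
        blocks = list(different_chromosome_pairs(genes, ann, block_size=7))
        pairs = [p for b in blocks for p in b]
        assert len(pairs) == 33
        assert len(set(pairs)) == 33

    def test_scored_pair_count_and_thresholds(self, fixture_cohort):
        c = fixture_cohort
        labels = c.labels
        from synlethal.pair_features import FeatureConfig, build_feature_table
        feat_cfg = FeatureConfig(high_deletion_threshold=100)
        pairs = list(zip(labels.pairs["gene_a"], labels.pairs["gene_b"]))
        feats = build_feature_table(pairs, c.cnv, c.expr_status, feat_cfg)
        cfg = EnsembleConfig(n_undersample_replicates=1, n_estimators=5)
        model = train_ensemble(feats, labels, cfg, seed=0)

        preds, summary = predict_genome_wide(
            model, c.cnv.gene_ids, c.annotation, c.cnv, c.expr_status,
            threshold=0.0, feature_config=feat_cfg, block_size=50)
        # 20 genes round-robin on 6 chromosomes: sizes 4,4,3,3,3,3
        expected = 190 - (6 + 6 + 3 + 3 + 3 + 3)
        assert summary["n_pairs_scored"] == expected
        assert len(preds) == expected  # threshold 0 keeps everything

        with pytest.raises(ValueError):
            predict_genome_wide(model, c.cnv.gene_ids, c.annotation, c.cnv,
                                c.expr_status, threshold=1.01)
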