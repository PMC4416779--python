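"""Under-sampled, mean-combined ensemble classifier for SL pair prediction.

Known SL pairs are rare (about 4.6% of labeled pairs), so every training set
is first balanced by randomly under-sampling the negative class to the size of
the positive class. Seven probabilistic base learners are trained on each
balanced replicate and the final score is the plain mean of all base-learner
probabilities across replicates:

    p(x) = (1/N) * sum_i p_i(x)

The seven default learner families mirror a boosted-stump / pruned-tree /
logit-boosting / random-forest / logistic-regression / rule-style line-up;
rule-list inducers have no scikit-learn counterpart, so those two slots are
filled by a shallow decision tree (a rule-list-like partition) and
extremely-randomized trees. All learners are swappable through
:class:`EnsembleConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .io_formats import (
    CNVMatrix,
    ExpressionStatusMatrix,
    GeneAnnotation,
    LabeledPairSet,
    PredictionTable,
)
from .pair_features import FRACTION_COLUMNS, FeatureConfig, build_feature_table

logger = logging.getLogger(__name__)


def default_base_learners(seed: int = 0, n_estimators: int = 50) -> list[tuple[str, object]]:
    """The seven default base-learner prototypes (unfitted)."""
    return [
        ("adaboost", AdaBoostClassifier(n_estimators=n_estimators, random_state=seed)),
        ("pruned_tree", DecisionTreeClassifier(
            min_samples_leaf=5, ccp_alpha=0.005, random_state=seed)),
        ("logit_boost", GradientBoostingClassifier(
            n_estimators=n_estimators, random_state=seed)),
        ("random_forest", RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed)),
        ("logistic", LogisticRegression(max_iter=2000)),
        ("rule_tree", DecisionTreeClassifier(
            max_depth=3, min_samples_leaf=10, random_state=seed)),
        ("extra_trees", ExtraTreesClassifier(
            n_estimators=n_estimators, random_state=seed)),
    ]


@dataclass
class EnsembleConfig:
    feature_columns: list[str] = field(default_factory=lambda: list(FRACTION_COLUMNS))
    n_undersample_replicates: int = 10  # 100 to mirror the original protocol
    n_estimators: int = 50
    base_learners: list[tuple[str, object]] | None = None  # None -> the 7 defaults

    def learners(self, seed: int) -> list[tuple[str, object]]:
        if self.base_learners is not None:
            return [(name, clone(est)) for name, est in self.base_learners]
        return default_base_learners(seed, self.n_estimators)


def undersample_negatives(labels: LabeledPairSet, seed: int = 0) -> LabeledPairSet:
    """Balance classes: keep every SL pair, sample non-SL pairs down to match."""
    df = labels.pairs
    pos = df[df["label"] == "SL"]
    neg = df[df["label"] == "nonSL"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one pair in each class")
    if len(neg) < len(pos):
        logger.warning("fewer negatives (%d) than positives (%d); keeping all",
                       len(neg), len(pos))
        sampled = neg
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        sampled = neg.iloc[np.sort(idx)]
    return LabeledPairSet(pd.concat([pos, sampled], ignore_index=True))


def _feature_frame(features: pd.DataFrame, pairs: pd.DataFrame, columns) -> pd.DataFrame:
    indexed = features.set_index(["gene_a", "gene_b"])
    missing = [c for c in columns if c not in indexed.columns]
    if missing:
        raise KeyError(f"unknown feature column(s): {missing}")
    idx = pd.MultiIndex.from_frame(pairs[["gene_a", "gene_b"]])
    return indexed.reindex(idx)[list(columns)]


@dataclass
class EnsembleModel:
    """Trained ensemble: learners per under-sample replicate + imputation constants."""

    replicates: list[list[tuple[str, object]]]
    impute_values: dict[str, float]
    feature_columns: list[str]
    seed: int

    @property
    def n_learners(self) -> int:
        return sum(len(r) for r in self.replicates)

    def _impute(self, X: pd.DataFrame) -> np.ndarray:
        X = X[self.feature_columns].copy()
        for col, val in self.impute_values.items():
            X[col] = X[col].fillna(val)
        return X.to_numpy(dtype=float)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Mean SL probability over all replicates and base learners."""
        missing = [c for c in self.feature_columns if c not in X.columns]
        if missing:
            raise KeyError(f"unknown feature column(s): {missing}")
        if len(X) == 0:
            return np.empty(0)
        Xn = self._impute(X)
        total = np.zeros(len(Xn))
        for learners in self.replicates:
            for _, est in learners:
                pos = list(est.classes_).index(1)
                total += est.predict_proba(Xn)[:, pos]
        return total / self.n_learners


def train_ensemble(
    features: pd.DataFrame,
    labels: LabeledPairSet,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
) -> EnsembleModel:
    """Fit the ensemble on labeled pairs.

    For each of ``n_undersample_replicates`` balanced sets, all base learners
    are fitted; feature medians for NaN imputation come from the training
    pairs only.
    """
    train_X = _feature_frame(features, labels.pairs, config.feature_columns)
    impute = {c: float(np.nanmedian(train_X[c])) if train_X[c].notna().any() else 0.0
              for c in config.feature_columns}

    rng = np.random.default_rng(seed)
    replicates = []
    for r in range(config.n_undersample_replicates):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        balanced = undersample_negatives(labels, seed=sub_seed)
        if balanced.n_positive < 2 or balanced.n_negative < 1:
            raise ValueError("need at least 2 examples per class after under-sampling")
        Xb = _feature_frame(features, balanced.pairs, config.feature_columns)
        for col, val in impute.items():
            Xb[col] = Xb[col].fillna(val)
        yb = (balanced.pairs["label"] == "SL").to_numpy(dtype=int)
        if len(set(yb)) < 2:
            raise ValueError("degenerate single-class training set")
        fitted = []
        for name, est in config.learners(sub_seed % (2**31 - 1)):
            est = clone(est)
            est.fit(Xb.to_numpy(dtype=float), yb)
            fitted.append((name, est))
        replicates.append(fitted)
    return EnsembleModel(replicates, impute, list(config.feature_columns), seed)


def ensemble_predict(
    model: EnsembleModel, features: pd.DataFrame, threshold: float = 0.81
) -> PredictionTable:
    """Score a feature table and return a thresholded prediction table."""
    if len(features) == 0:
        empty = pd.DataFrame(columns=["gene_a", "gene_b", "probability", "call"])
        return PredictionTable(empty, threshold)
    p = model.predict_proba(features)
    return PredictionTable.from_probabilities(
        features["gene_a"], features["gene_b"], p, threshold)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties between classes count one half."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def precision_recall_points(scores, labels) -> pd.DataFrame:
    """Precision and recall at every distinct score threshold, descending.

    A row's precision/recall treat scores >= threshold as positive calls.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    precision, recall, thresholds = _sk_pr_curve(labels, scores)
    # sklearn orders thresholds ascending and appends the (1, 0) endpoint
    df = pd.DataFrame({
        "threshold": thresholds[::-1],
        "precision": precision[:-1][::-1],
        "recall": recall[:-1][::-1],
    })
    return df.reset_index(drop=True)


# kept as the operation name users expect
precision_recall = precision_recall_points


def select_threshold(pr: pd.DataFrame, target_precision: float) -> tuple[float, float, float]:
    """Smallest threshold whose precision reaches ``target_precision``.

    Returns ``(threshold, precision, recall)`` at that point; raises when the
    target is unreachable, naming the best achievable precision.
    """
    if len(pr) == 0:
        raise ValueError("empty precision-recall curve")
    ok = pr[pr["precision"] >= target_precision]
    if len(ok) == 0:
        raise ValueError(
            f"target precision {target_precision} unreachable; "
            f"maximum achievable is {pr['precision'].max():.4f}")
    row = ok.loc[ok["threshold"].idxmin()]
    return float(row["threshold"]), float(row["precision"]), float(row["recall"])


@dataclass
class CVResult:
    fold_aucs: pd.DataFrame      # columns repeat, fold, auc
    repeat_aucs: np.ndarray      # pooled out-of-fold AUC per repeat
    mean_auc: float
    se_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray         # vertically averaged ROC
    se_tpr: np.ndarray
    recall_grid: np.ndarray
    mean_precision: np.ndarray   # averaged PR curve
    se_precision: np.ndarray
    pooled_pr: pd.DataFrame      # PR points of the last repeat's pooled scores


def cross_validate(
    features: pd.DataFrame,
    labels: LabeledPairSet,
    k: int = 10,
    repeats: int = 10,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold evaluation of the ensemble.

    Under-sampling and imputation happen inside each training fold only; test
    folds keep the natural class imbalance. The mean AUC is the mean of the
    per-repeat pooled out-of-fold AUCs; the mean ROC is vertically averaged on
    a 101-point false-positive-rate grid, the PR curve on a recall grid.
    """
    df = labels.pairs
    y = (df["label"] == "SL").to_numpy(dtype=int)
    if y.sum() < k or (1 - y).sum() < k:
        raise ValueError(f"fewer than k={k} examples in a class")
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0, 1, 101)
    recall_grid = np.linspace(0, 1, 101)

    fold_rows, repeat_aucs, tprs, precs = [], [], [], []
    pooled_pr = None
    for rep in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        oof = np.full(len(df), np.nan)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(df)), y)):
            train_labels = LabeledPairSet(df.iloc[tr].reset_index(drop=True))
            model = train_ensemble(features, train_labels, config,
                                   seed=(rep_seed + fold) % (2**31 - 1))
            test_X = _feature_frame(features, df.iloc[te], config.feature_columns)
            oof[te] = model.predict_proba(test_X)
            fold_rows.append({"repeat": rep, "fold": fold,
                              "auc": roc_auc(oof[te], y[te])})
        repeat_aucs.append(roc_auc(oof, y))
        fpr, tpr, _ = roc_curve(y, oof)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
        pr = precision_recall_points(oof, y)
        order = np.argsort(pr["recall"].to_numpy())
        precs.append(np.interp(recall_grid,
                               pr["recall"].to_numpy()[order],
                               pr["precision"].to_numpy()[order]))
        pooled_pr = pr

    repeat_aucs = np.asarray(repeat_aucs)
    tprs = np.vstack(tprs)
    precs = np.vstack(precs)
    n = len(repeat_aucs)
    return CVResult(
        fold_aucs=pd.DataFrame(fold_rows),
        repeat_aucs=repeat_aucs,
        mean_auc=float(repeat_aucs.mean()),
        se_auc=float(repeat_aucs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        fpr_grid=fpr_grid,
        mean_tpr=tprs.mean(axis=0),
        se_tpr=tprs.std(ddof=1, axis=0) / np.sqrt(n) if n > 1 else np.zeros_like(fpr_grid),
        recall_grid=recall_grid,
        mean_precision=precs.mean(axis=0),
        se_precision=(precs.std(ddof=1, axis=0) / np.sqrt(n)
                      if n > 1 else np.zeros_like(recall_grid)),
        pooled_pr=pooled_pr,
    )


def different_chromosome_pairs(genes, annotation: GeneAnnotation, block_size: int = 100_000):
    """Yield blocks of different-chromosome gene pairs without materializing all."""
    genes = [g for g in genes if g in annotation]
    block = []
    for a, b in combinations(sorted(genes), 2):
        if annotation.chromosome(a) != annotation.chromosome(b):
            block.append((a, b))
            if len(block) >= block_size:
                yield block
                block = []
    if block:
        yield block


def predict_genome_wide(
    model: EnsembleModel,
    all_genes,
    annotation: GeneAnnotation,
    cnv: CNVMatrix,
    expr_status: ExpressionStatusMatrix,
    threshold: float = 0.81,
    feature_config: FeatureConfig = FeatureConfig(),
    block_size: int = 100_000,
) -> tuple[PredictionTable, dict]:
    """Score every different-chromosome pair in the gene universe.

    The universe is restricted to genes present in both matrices; pairs are
    streamed in blocks. Returns the pairs scoring at or above ``threshold``
    and a summary with the scored-pair count.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    universe = [g for g in all_genes if g in cnv and g in expr_status]
    kept_frames = []
    n_scored = 0
    for block in different_chromosome_pairs(universe, annotation, block_size):
        feats = build_feature_table(block, cnv, expr_status, feature_config)
        if len(feats) == 0:
            continue
        p = model.predict_proba(feats)
        n_scored += len(feats)
        keep = p >= threshold
        if keep.any():
            kept_frames.append(pd.DataFrame({
                "gene_a": feats.loc[keep, "gene_a"].to_numpy(),
                "gene_b": feats.loc[keep, "gene_b"].to_numpy(),
                "probability": p[keep],
            }))
    if kept_frames:
        out = pd.concat(kept_frames, ignore_index=True)
        out["call"] = "SL"
    else:
        out = pd.DataFrame(columns=["gene_a", "gene_b", "probability", "call"])
    summary = {"n_universe_genes": len(universe), "n_pairs_scored": n_scored,
               "n_pairs_above_threshold": len(out), "threshold": threshold}
    logger.info("genome-wide prediction: %s", summary)
    return PredictionTable(out, threshold), summary
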