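"""End-to-end orchestration: pattern analysis, model training/evaluation,
genome-wide prediction.

Each run writes its outputs plus a ``manifest.json`` recording the config
hash, seeds and input checksums, so deterministic stages reproduce
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensemble_model as em
from . import io_formats as io
from . import pair_features as pf
from . import pattern_stats as ps
from .expression_status import StatusCallConfig, call_status_matrix
from .synthetic_data import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cnv_path: str | None = None
    expr_status_path: str | None = None
    expr_path: str | None = None
    expr_meta_path: str | None = None
    annotation_path: str | None = None
    labels_path: str | None = None
    model_path: str | None = None
    outdir: str = "synlethal_out"
    seed: int = 0
    status: StatusCallConfig = field(default_factory=StatusCallConfig)
    features: pf.FeatureConfig = field(default_factory=pf.FeatureConfig)
    patterns: ps.PatternConfig = field(default_factory=ps.PatternConfig)
    model: em.EnsembleConfig = field(default_factory=em.EnsembleConfig)
    cv_folds: int = 10
    cv_repeats: int = 10
    threshold: float = 0.81
    make_figures: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: dict[str, str],
                    extra: dict | None = None) -> None:
    def _jsonable(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: _jsonable(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj if isinstance(obj, (int, float, str, bool, type(None))) else str(obj)

    cfg = _jsonable(config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "input_sha256": {k: _sha256(Path(v)) for k, v in inputs.items() if v},
    }
    if extra:
        manifest.update(extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _load_common(config: RunConfig):
    for name in ("cnv_path", "expr_status_path", "annotation_path"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{name} missing or does not exist: {p}")
    cnv = io.read_cnv_matrix(config.cnv_path)
    expr_status = io.read_expression_status_matrix(config.expr_status_path)
    annotation = io.read_gene_annotation(config.annotation_path)
    return cnv, expr_status, annotation


def run_simulate(config: SyntheticCohortConfig, outdir) -> dict:
    """Generate a synthetic cohort and write it in the standard TSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    io.write_matrix(cohort.cnv, outdir / "cnv.tsv")
    io.write_matrix(cohort.expr_status, outdir / "expr_status.tsv")
    io.write_gene_annotation(cohort.annotation, outdir / "annotation.tsv")
    io.write_pair_labels(cohort.labels, outdir / "labels.tsv")
    summary = {"n_genes": config.n_genes,
               "n_samples": len(cohort.cnv.sample_ids),
               "n_sl": cohort.labels.n_positive,
               "n_nonsl": cohort.labels.n_negative}
    logger.info("simulated cohort: %s", summary)
    return summary


def run_call_expression_status(config: RunConfig) -> Path:
    """Continuous expression + metadata -> ternary status TSV."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression_matrix(config.expr_path, config.expr_meta_path)
    status = call_status_matrix(expr, config.status)
    out = outdir / "expr_status.tsv"
    io.write_matrix(status, out)
    _write_manifest(outdir, config,
                    {"expr": config.expr_path, "expr_meta": config.expr_meta_path})
    return out


def run_features(config: RunConfig) -> pd.DataFrame:
    """Chromosome-filter the labeled pairs and compute their feature table."""
    cnv, expr_status, annotation = _load_common(config)
    labels = io.read_pair_labels(config.labels_path)
    n_before = (labels.n_positive, labels.n_negative)
    filtered = pf.exclude_same_chromosome(labels, annotation)
    logger.info("pair filter: %d SL -> %d, %d nonSL -> %d",
                n_before[0], filtered.n_positive, n_before[1], filtered.n_negative)
    pairs = list(zip(filtered.pairs["gene_a"], filtered.pairs["gene_b"]))
    features = pf.build_feature_table(pairs, cnv, expr_status, config.features)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    io.write_pair_labels(filtered, outdir / "labels_filtered.tsv")
    _write_manifest(outdir, config, {
        "cnv": config.cnv_path, "expr_status": config.expr_status_path,
        "annotation": config.annotation_path, "labels": config.labels_path})
    return features


def run_pattern_analysis(config: RunConfig) -> pd.DataFrame:
    """Fractions + pattern statistics for the labeled pairs; writes report and figure."""
    cnv, expr_status, annotation = _load_common(config)
    labels = io.read_pair_labels(config.labels_path)
    filtered = pf.exclude_same_chromosome(labels, annotation)
    logger.info("pattern analysis on %d SL / %d nonSL pairs (from %d / %d)",
                filtered.n_positive, filtered.n_negative,
                labels.n_positive, labels.n_negative)
    feat_cfg = pf.FeatureConfig(
        high_deletion_threshold=config.features.high_deletion_threshold,
        filter_all_cnv_fractions=config.features.filter_all_cnv_fractions,
        include_genomic_updown=True,
    )
    pairs = list(zip(filtered.pairs["gene_a"], filtered.pairs["gene_b"]))
    features = pf.build_feature_table(pairs, cnv, expr_status, feat_cfg)
    pattern_cfg = config.patterns
    pattern_cfg.feature_config = feat_cfg
    report = ps.pattern_report(features, filtered, cnv, expr_status, annotation,
                               pattern_cfg, seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "pattern_report.tsv", sep="\t", index=False)
    _write_text_summary(report, outdir / "pattern_report.txt")
    if config.make_figures:
        _strip_plot(features, filtered, outdir / "fraction_stripplot.png")
    _write_manifest(outdir, config, {
        "cnv": config.cnv_path, "expr_status": config.expr_status_path,
        "annotation": config.annotation_path, "labels": config.labels_path})
    return report


def _write_text_summary(report: pd.DataFrame, path: Path) -> None:
    lines = ["pattern analysis summary", "=" * 30]
    for _, r in report.iterrows():
        if r["kind"] == "fraction":
            lines.append(
                f"{r['test']}: SL mean {r['sl_mean']:.4g} vs nonSL {r['nonsl_mean']:.4g} "
                f"({r['direction']}); Wilcoxon P_adj = {r['p_wilcoxon_adj']:.3g}; "
                f"randomization P_adj = {r['p_random_adj']:.3g}")
        else:
            lines.append(
                f"{r['test']}: {r['sl_mean']:.4g} vs {r['nonsl_mean']:.4g} "
                f"({r['direction']}); P = {r['p_wilcoxon']:.3g}")
    path.write_text("\n".join(lines) + "\n")


def _strip_plot(features: pd.DataFrame, labels, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    merged = features.merge(labels.pairs, on=["gene_a", "gene_b"])
    cols = [c for c in ("f1", "f2", "f3", "f4", "f5", "f6") if c in merged.columns]
    fig, axes = plt.subplots(1, len(cols), figsize=(2.2 * len(cols), 3.2), sharey=False)
    rng = np.random.default_rng(0)
    for ax, col in zip(np.atleast_1d(axes), cols):
        for i, lab in enumerate(("SL", "nonSL")):
            vals = merged.loc[merged["label"] == lab, col].dropna()
            x = i + rng.uniform(-0.15, 0.15, size=len(vals))
            ax.plot(x, vals, ".", markersize=2, alpha=0.4)
            if len(vals):
                ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="black")
        ax.set_xticks([0, 1], ["SL", "nonSL"])
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_train_eval(config: RunConfig) -> em.CVResult:
    """Cross-validated evaluation plus a final model refit on all labeled pairs."""
    cnv, expr_status, annotation = _load_common(config)
    labels = io.read_pair_labels(config.labels_path)
    filtered = pf.exclude_same_chromosome(labels, annotation)
    pairs = list(zip(filtered.pairs["gene_a"], filtered.pairs["gene_b"]))
    features = pf.build_feature_table(pairs, cnv, expr_status, config.features)

    cv = em.cross_validate(features, filtered, k=config.cv_folds,
                           repeats=config.cv_repeats, config=config.model,
                           seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cv_result.json", "w") as fh:
        json.dump({
            "mean_auc": cv.mean_auc, "se_auc": cv.se_auc,
            "repeat_aucs": cv.repeat_aucs.tolist(),
            "k": config.cv_folds, "repeats": config.cv_repeats,
        }, fh, indent=2)
    pd.DataFrame({"fpr": cv.fpr_grid, "mean_tpr": cv.mean_tpr,
                  "se_tpr": cv.se_tpr}).to_csv(outdir / "roc_curve.tsv",
                                               sep="\t", index=False)
    pd.DataFrame({"recall": cv.recall_grid, "mean_precision": cv.mean_precision,
                  "se_precision": cv.se_precision}).to_csv(
        outdir / "pr_curve.tsv", sep="\t", index=False)
    cv.fold_aucs.to_csv(outdir / "fold_aucs.tsv", sep="\t", index=False)

    model = em.train_ensemble(features, filtered, config.model, seed=config.seed)
    archive = {
        "model": model,
        "manifest": {
            "learner_families": [name for name, _ in model.replicates[0]],
            "n_replicates": len(model.replicates),
            "impute_values": model.impute_values,
            "feature_columns": model.feature_columns,
            "seed": config.seed,
        },
    }
    with open(outdir / "model.pkl", "wb") as fh:
        pickle.dump(archive, fh)
    _write_manifest(outdir, config, {
        "cnv": config.cnv_path, "expr_status": config.expr_status_path,
        "annotation": config.annotation_path, "labels": config.labels_path},
        extra={"mean_auc": cv.mean_auc})
    return cv


def run_predict(config: RunConfig) -> tuple[io.PredictionTable, dict]:
    """Genome-wide different-chromosome prediction with a trained model archive."""
    cnv, expr_status, annotation = _load_common(config)
    if config.model_path is None or not Path(config.model_path).exists():
        raise FileNotFoundError(f"model archive missing: {config.model_path}")
    with open(config.model_path, "rb") as fh:
        archive = pickle.load(fh)
    model = archive["model"]
    universe = sorted(set(cnv.gene_ids) & set(expr_status.gene_ids))
    preds, summary = em.predict_genome_wide(
        model, universe, annotation, cnv, expr_status,
        threshold=config.threshold, feature_config=config.features)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_predictions(preds, outdir / "predictions.tsv")
    _write_manifest(outdir, config, {
        "cnv": config.cnv_path, "expr_status": config.expr_status_path,
        "annotation": config.annotation_path, "model": config.model_path},
        extra={"summary": summary})
    logger.info("prediction summary: %s", summary)
    return preds, summary
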