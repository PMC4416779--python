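"""Statistical comparison of fraction patterns between SL, non-SL and random pairs.

Two complementary tests per fraction:

* a one-sided two-sample Wilcoxon rank-sum test of SL versus non-SL fraction
  values (exact by enumeration when the combined sample is small and tie-free,
  normal approximation with tie and continuity corrections otherwise);
* an empirical randomization test: repeated draws of random different-chromosome
  gene pairs, comparing each draw's mean fraction with the SL mean in the
  direction the pattern predicts. With ``n_rand`` draws and ``n1`` draws
  contradicting the expectation, p = (n1 + 1) / (n_rand + 1).

Multiple testing is handled per family with Bonferroni: the four co-loss
fractions (f1-f4) form one family, the two up-down fractions (f5, and the
optional genomic up-down f6) the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CNVMatrix, ExpressionStatusMatrix, GeneAnnotation, LabeledPairSet
from .pair_features import (
    EVENTS,
    FRACTION_EVENTS,
    FeatureConfig,
    event_counts,
    flag_high_deletion_samples,
    single_loss_rate,
)

logger = logging.getLogger(__name__)

# f1-f4: SL fractions are expected to be smaller (co-loss suppressed);
# f5/f6: larger (compensation enriched).
EXPECTED_DIRECTION = {"f1": "less", "f2": "less", "f3": "less", "f4": "less",
                      "f5": "greater", "f6": "greater"}
FAMILY = {"f1": "co_loss", "f2": "co_loss", "f3": "co_loss", "f4": "co_loss",
          "f5": "up_down", "f6": "up_down"}
FAMILY_SIZE = {"co_loss": 4, "up_down": 2}


def wilcoxon_one_sided(x, y, alternative: str) -> float:
    """One-sided two-sample rank-sum (Mann-Whitney) p-value.

    Exact when the combined sample size is at most 20 with no ties, otherwise
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


@dataclass
class RandomizationConfig:
    n_rand: int = 1000
    n_pairs_per_draw: int = 300


@dataclass
class RandomizationResult:
    fraction: str
    n_rand: int
    n_pairs_per_draw: int
    n1: int  # draws contradicting the expected direction (ties included)
    sl_mean: float
    random_mean: float  # grand mean over draws

    @property
    def p(self) -> float:
        return (self.n1 + 1) / (self.n_rand + 1)


def draw_random_pairs(
    genes, annotation: GeneAnnotation, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs of distinct different-chromosome genes, without replacement.

    Returns positions into ``genes``; rejection-samples candidate pairs so the
    draw is uniform over admissible unordered pairs.
    """
    genes = list(genes)
    n = len(genes)
    if n < 2:
        raise ValueError("gene pool too small to draw pairs")
    chrom = np.asarray([annotation.chromosome(g) for g in genes], dtype=object)
    if len({c for c in chrom if c is not None}) < 2:
        raise ValueError("gene pool spans fewer than 2 chromosomes")
    chosen: set[tuple[int, int]] = set()
    out_a, out_b = [], []
    attempts = 0
    while len(out_a) < n_pairs:
        attempts += 1
        if attempts > 200 * n_pairs + 1000:
            raise ValueError(
                f"gene pool too small: could not draw {n_pairs} distinct "
                f"different-chromosome pairs")
        i, j = rng.integers(0, n, size=2)
        if i == j or chrom[i] is None or chrom[j] is None or chrom[i] == chrom[j]:
            continue
        key = (min(i, j), max(i, j))
        if key in chosen:
            continue
        chosen.add(key)
        out_a.append(key[0])
        out_b.append(key[1])
    return np.asarray(out_a, dtype=np.intp), np.asarray(out_b, dtype=np.intp)


def randomization_test(
    sl_values,
    gene_pool,
    annotation: GeneAnnotation,
    matrix: CNVMatrix | ExpressionStatusMatrix,
    fraction_name: str,
    config: RandomizationConfig = RandomizationConfig(),
    seed: int = 0,
    excluded_samples=(),
) -> RandomizationResult:
    """Empirical randomization null for one fraction.

    ``sl_values`` are the SL pairs' defined fraction values; ``gene_pool``
    the genes eligible for random pairing (genes with both data types),
    all present in ``matrix``. Each draw's mean fraction (over defined values)
    is compared with the SL mean in the expected direction; ties count as
    contradictions.
    """
    sl_values = np.asarray(sl_values, dtype=float)
    sl_values = sl_values[~np.isnan(sl_values)]
    if sl_values.size == 0:
        raise ValueError("no defined SL fraction values")
    sl_mean = float(sl_values.mean())
    direction = EXPECTED_DIRECTION[fraction_name]
    event = EVENTS[FRACTION_EVENTS[fraction_name]]
    rng = np.random.default_rng(seed)
    genes = list(gene_pool)
    gene_idx = matrix.gene_indices(genes)

    n1 = 0
    means = np.empty(config.n_rand)
    for r in range(config.n_rand):
        ia, ib = draw_random_pairs(genes, annotation, config.n_pairs_per_draw, rng)
        n_event, n_t = event_counts(matrix, gene_idx[ia], gene_idx[ib], event,
                                    excluded_samples)
        defined = n_t > 0
        if not defined.any():
            means[r] = np.nan
            n1 += 1  # a draw with no information cannot support the signal
            continue
        m = float((n_event[defined] / n_t[defined]).mean())
        means[r] = m
        # expectation: SL mean below (f1-f4) / above (f5-f6) the random mean
        contradicts = (m <= sl_mean) if direction == "less" else (m >= sl_mean)
        if contradicts:
            n1 += 1
    return RandomizationResult(
        fraction=fraction_name,
        n_rand=config.n_rand,
        n_pairs_per_draw=config.n_pairs_per_draw,
        n1=n1,
        sl_mean=sl_mean,
        random_mean=float(np.nanmean(means)),
    )


@dataclass
class PatternConfig:
    randomization: RandomizationConfig = field(default_factory=RandomizationConfig)
    include_genomic_updown: bool = True
    n_control_random_genes: int = 300
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)


def _fraction_values(features: pd.DataFrame, pair_index, column: str) -> np.ndarray:
    sub = features.set_index(["gene_a", "gene_b"]).reindex(pair_index)
    vals = sub[column].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def pattern_report(
    features: pd.DataFrame,
    labels: LabeledPairSet,
    cnv: CNVMatrix,
    expr_status: ExpressionStatusMatrix,
    annotation: GeneAnnotation,
    config: PatternConfig = PatternConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Full pattern comparison: six fraction rows plus two gene-level controls.

    Per fraction: SL / non-SL / random means, one-sided Wilcoxon p
    (SL vs non-SL), randomization p, both Bonferroni-adjusted within their
    family (4 co-loss members, 2 up-down members). Setting
    ``config.randomization.n_rand`` to 0 skips the randomization columns
    (reported as NaN). A fraction with all-missing values is reported as
    not testable rather than raising.
    """
    lab = labels.pairs
    sl_index = pd.MultiIndex.from_frame(lab.loc[lab["label"] == "SL", ["gene_a", "gene_b"]])
    nonsl_index = pd.MultiIndex.from_frame(
        lab.loc[lab["label"] == "nonSL", ["gene_a", "gene_b"]])

    pool = sorted(
        g for g in set(cnv.gene_ids) & set(expr_status.gene_ids) if g in annotation
    )
    high_del = flag_high_deletion_samples(cnv, config.feature_config.high_deletion_threshold)

    fractions = ["f1", "f2", "f3", "f4", "f5"] + (
        ["f6"] if config.include_genomic_updown and "f6" in features.columns else [])
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        direction = EXPECTED_DIRECTION[frac]
        family_m = FAMILY_SIZE[FAMILY[frac]]
        sl_vals = _fraction_values(features, sl_index, frac)
        nonsl_vals = _fraction_values(features, nonsl_index, frac)
        row = {
            "test": frac,
            "kind": "fraction",
            "direction": direction,
            "family": FAMILY[frac],
            "n_sl": sl_vals.size,
            "n_nonsl": nonsl_vals.size,
            "sl_mean": float(sl_vals.mean()) if sl_vals.size else np.nan,
            "nonsl_mean": float(nonsl_vals.mean()) if nonsl_vals.size else np.nan,
            "random_mean": np.nan,
            "p_wilcoxon": np.nan, "p_wilcoxon_adj": np.nan,
            "p_random": np.nan, "p_random_adj": np.nan, "n1": np.nan,
            "testable": bool(sl_vals.size and nonsl_vals.size),
        }
        if row["testable"]:
            p = wilcoxon_one_sided(sl_vals, nonsl_vals, direction)
            row["p_wilcoxon"] = p
            row["p_wilcoxon_adj"] = bonferroni_adjust(p, family_m)
            if config.randomization.n_rand > 0:
                event = EVENTS[FRACTION_EVENTS[frac]]
                matrix = cnv if event.source == "cnv" else expr_status
                excl = high_del if frac == "f1" else ()
                res = randomization_test(
                    sl_vals, pool, annotation, matrix, frac,
                    config.randomization,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    excluded_samples=excl,
                )
                row["random_mean"] = res.random_mean
                row["n1"] = res.n1
                row["p_random"] = res.p
                row["p_random_adj"] = bonferroni_adjust(res.p, family_m)
        else:
            logger.warning("fraction %s has no defined values in a class; not testable", frac)
        rows.append(row)

    rows.extend(_gene_level_controls(labels, cnv, expr_status, pool, high_del,
                                     config, rng))
    return pd.DataFrame(rows)


def _gene_level_controls(labels, cnv, expr_status, pool, high_del, config, rng):
    """Single-gene controls: loss-rate and over-expression-rate comparisons."""
    sl_genes = [g for g in labels.genes("SL") if g in cnv]
    nonsl_genes = [g for g in labels.genes("nonSL") if g in cnv]
    rows = []

    # homozygous deletion rate: SL genes vs non-SL genes, two-sided
    if sl_genes and nonsl_genes:
        sl_rates = [single_loss_rate(g, cnv, -2) for g in sl_genes]
        nonsl_rates = [single_loss_rate(g, cnv, -2) for g in nonsl_genes]
        p = float(stats.mannwhitneyu(sl_rates, nonsl_rates, alternative="two-sided").pvalue)
        rows.append({
            "test": "hom_deletion_rate", "kind": "gene_control", "direction": "two-sided",
            "family": "control", "n_sl": len(sl_rates), "n_nonsl": len(nonsl_rates),
            "sl_mean": float(np.mean(sl_rates)), "nonsl_mean": float(np.mean(nonsl_rates)),
            "random_mean": np.nan, "p_wilcoxon": p, "p_wilcoxon_adj": p,
            "p_random": np.nan, "p_random_adj": np.nan, "n1": np.nan, "testable": True,
        })

    # over-expression rate: non-SL genes vs random genes, one-sided (greater)
    nonsl_expr = [g for g in labels.genes("nonSL") if g in expr_status]
    n_draw = min(config.n_control_random_genes, len(pool))
    if nonsl_expr and n_draw >= 2:
        random_genes = list(rng.choice(pool, size=n_draw, replace=False))
        nonsl_rates = [single_loss_rate(g, expr_status, 1) for g in nonsl_expr]
        rand_rates = [single_loss_rate(g, expr_status, 1) for g in random_genes]
        p = wilcoxon_one_sided(nonsl_rates, rand_rates, "greater")
        rows.append({
            "test": "overexpression_rate", "kind": "gene_control", "direction": "greater",
            "family": "control", "n_sl": len(nonsl_rates), "n_nonsl": len(rand_rates),
            "sl_mean": float(np.mean(nonsl_rates)), "nonsl_mean": float(np.mean(rand_rates)),
            "random_mean": np.nan, "p_wilcoxon": p, "p_wilcoxon_adj": p,
            "p_random": np.nan, "p_random_adj": np.nan, "n1": np.nan, "testable": True,
        })
    return rows
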