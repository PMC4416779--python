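"""Simulated tumor cohorts with planted synthetic-lethal pair structure.

Background genes receive independent per-sample categorical draws of CNV
status (codes -2..2) and expression status (-1, 0, 1). For each planted SL
pair the per-sample joint distribution over the two genes' statuses is the
product of the marginals, reweighted and renormalized:

* co-loss cells (both genes in {-1, -2} for CNV; both -1 for expression)
  are multiplied by a suppression factor ``rho`` in [0, 1];
* up-down cells (one gene in {1, 2} while the other is in {-1, -2}; for
  expression, (-1, 1) and (1, -1)) are multiplied by an enrichment factor
  ``kappa`` >= 1.

``rho = kappa = 1`` gives an exchangeable null cohort. Optional hyper-deleted
samples draw every gene's homozygous-deletion probability at an elevated
rate, exercising the high-deletion sample filter. Default background rates
are scaled for a 500-sample cohort so every fraction has non-degenerate
denominators (see ``DEFAULT_CNV_PROBS``); ``TCGA_SCALE_*`` carry the
panel-scale per-gene rates (homozygous deletion ~0.004, heterozygous ~0.1,
under-expression ~0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    CNVMatrix,
    ExpressionMatrix,
    ExpressionStatusMatrix,
    GeneAnnotation,
    LabeledPairSet,
)
import pandas as pd

CNV_CODE_ORDER = (-2, -1, 0, 1, 2)
EXPR_CODE_ORDER = (-1, 0, 1)

# Rates for the default desk-scale cohort (500 samples). Real tumor panels
# show per-gene homozygous-deletion rates near 0.004 — but over ~14k samples;
# at 500 samples that leaves the homozygous co-loss fraction with no events at
# all. The defaults scale the loss/over-expression rates up so per-gene event
# counts at 500 samples sit in the same informative regime (~15 deleted
# samples per gene); panel-scale rates are available as TCGA_SCALE_*.
DEFAULT_CNV_PROBS = {-2: 0.03, -1: 0.12, 0: 0.79, 1: 0.04, 2: 0.02}
DEFAULT_EXPR_PROBS = {-1: 0.08, 0: 0.84, 1: 0.08}

# per-gene status rates at the scale of a ~14k-sample pan-cancer panel
TCGA_SCALE_CNV_PROBS = {-2: 0.004, -1: 0.10, 0: 0.846, 1: 0.04, 2: 0.01}
TCGA_SCALE_EXPR_PROBS = {-1: 0.05, 0: 0.90, 1: 0.05}


@dataclass
class SyntheticCohortConfig:
    n_genes: int = 2000
    n_samples: int = 500
    n_chromosomes: int = 22
    cnv_probs: dict = field(default_factory=lambda: dict(DEFAULT_CNV_PROBS))
    expr_probs: dict = field(default_factory=lambda: dict(DEFAULT_EXPR_PROBS))
    n_sl_pairs: int = 100
    n_nonsl_pairs: int = 2000
    rho: float = 0.2        # co-loss suppression for planted pairs
    kappa: float = 3.0      # up-down enrichment for planted pairs
    n_heavy_deletion_samples: int = 5
    heavy_deletion_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        for probs, order in ((self.cnv_probs, CNV_CODE_ORDER),
                             (self.expr_probs, EXPR_CODE_ORDER)):
            total = sum(probs.get(c, 0.0) for c in order)
            if not np.isclose(total, 1.0):
                raise ValueError(f"status probabilities must sum to 1, got {total}")
        if 2 * self.n_sl_pairs > self.n_genes:
            raise ValueError("not enough genes for the requested planted SL pairs")


@dataclass
class SyntheticCohort:
    cnv: CNVMatrix
    expr_status: ExpressionStatusMatrix
    annotation: GeneAnnotation
    labels: LabeledPairSet
    config: SyntheticCohortConfig


def _joint_distribution(marginal: np.ndarray, codes, rho: float, kappa: float,
                        co_loss_codes, up_codes, down_codes) -> np.ndarray:
    """Reweighted product distribution over ordered status cells."""
    joint = np.outer(marginal, marginal)
    for i, a in enumerate(codes):
        for j, b in enumerate(codes):
            if a in co_loss_codes and b in co_loss_codes:
                joint[i, j] *= rho
            elif (a in up_codes and b in down_codes) or (a in down_codes and b in up_codes):
                joint[i, j] *= kappa
    return joint / joint.sum()


def cnv_pair_joint(config: SyntheticCohortConfig) -> np.ndarray:
    marg = np.array([config.cnv_probs.get(c, 0.0) for c in CNV_CODE_ORDER])
    return _joint_distribution(marg, CNV_CODE_ORDER, config.rho, config.kappa,
                               co_loss_codes={-2, -1}, up_codes={1, 2},
                               down_codes={-2, -1})


def expr_pair_joint(config: SyntheticCohortConfig) -> np.ndarray:
    marg = np.array([config.expr_probs.get(c, 0.0) for c in EXPR_CODE_ORDER])
    return _joint_distribution(marg, EXPR_CODE_ORDER, config.rho, config.kappa,
                               co_loss_codes={-1}, up_codes={1}, down_codes={-1})


def _draw_categorical(rng, probs: np.ndarray, codes, size) -> np.ndarray:
    idx = rng.choice(len(codes), p=probs, size=size)
    return np.asarray(codes, dtype=np.int8)[idx]


def _draw_joint(rng, joint: np.ndarray, codes, n: int) -> tuple[np.ndarray, np.ndarray]:
    flat = rng.choice(joint.size, p=joint.ravel(), size=n)
    ii, jj = np.unravel_index(flat, joint.shape)
    codes = np.asarray(codes, dtype=np.int8)
    return codes[ii], codes[jj]


def _chromosome_assignment(n_genes: int, n_chromosomes: int) -> list[str]:
    # round-robin keeps planted pairs (consecutive genes) on different chromosomes
    return [str(i % n_chromosomes + 1) for i in range(n_genes)]


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a full cohort: CNV + expression-status matrices, annotation, labels."""
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    genes = [f"G{i:05d}" for i in range(G)]
    samples = [f"T{j:04d}" for j in range(S)]
    chroms = _chromosome_assignment(G, config.n_chromosomes)
    annotation = GeneAnnotation(dict(zip(genes, chroms)))

    cnv_marg = np.array([config.cnv_probs.get(c, 0.0) for c in CNV_CODE_ORDER])
    expr_marg = np.array([config.expr_probs.get(c, 0.0) for c in EXPR_CODE_ORDER])
    cnv = _draw_categorical(rng, cnv_marg, CNV_CODE_ORDER, (G, S))
    expr = _draw_categorical(rng, expr_marg, EXPR_CODE_ORDER, (G, S))

    # planted SL pairs occupy the first 2*n_sl genes, consecutive indices:
    # round-robin chromosome assignment puts them on different chromosomes
    cnv_joint = cnv_pair_joint(config)
    expr_joint = expr_pair_joint(config)
    sl_pairs = []
    for k in range(config.n_sl_pairs):
        ia, ib = 2 * k, 2 * k + 1
        a, b = _draw_joint(rng, cnv_joint, CNV_CODE_ORDER, S)
        cnv[ia], cnv[ib] = a, b
        a, b = _draw_joint(rng, expr_joint, EXPR_CODE_ORDER, S)
        expr[ia], expr[ib] = a, b
        sl_pairs.append((genes[ia], genes[ib]))

    # labeled non-SL pairs come from background genes, different chromosomes
    background = np.arange(2 * config.n_sl_pairs, G)
    if len(background) < 2:
        raise ValueError("not enough background genes for non-SL pairs")
    nonsl, seen = [], set()
    attempts = 0
    while len(nonsl) < config.n_nonsl_pairs:
        attempts += 1
        if attempts > 200 * config.n_nonsl_pairs + 1000:
            raise ValueError("cannot draw the requested number of non-SL pairs")
        i, j = rng.choice(background, size=2, replace=False)
        if chroms[i] == chroms[j]:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        nonsl.append((genes[key[0]], genes[key[1]]))

    # optional hyper-deleted samples with an elevated homozygous-deletion rate
    if config.n_heavy_deletion_samples > 0:
        H = config.n_heavy_deletion_samples
        heavy_probs = cnv_marg.copy()
        extra = config.heavy_deletion_rate - heavy_probs[0]
        heavy_probs[0] = config.heavy_deletion_rate
        heavy_probs[2] -= extra  # take mass from the "normal" code
        if heavy_probs[2] < 0:
            raise ValueError("heavy_deletion_rate too high for background probabilities")
        heavy = _draw_categorical(rng, heavy_probs, CNV_CODE_ORDER, (G, H))
        cnv = np.concatenate([cnv, heavy], axis=1)
        heavy_expr = _draw_categorical(rng, expr_marg, EXPR_CODE_ORDER, (G, H))
        expr = np.concatenate([expr, heavy_expr], axis=1)
        samples = samples + [f"H{j:04d}" for j in range(H)]

    label_df = pd.DataFrame(
        [(a, b, "SL") for a, b in sl_pairs] + [(a, b, "nonSL") for a, b in nonsl],
        columns=["gene_a", "gene_b", "label"],
    )
    return SyntheticCohort(
        cnv=CNVMatrix(genes, samples, cnv),
        expr_status=ExpressionStatusMatrix(genes, list(samples), expr),
        annotation=annotation,
        labels=LabeledPairSet(label_df),
        config=config,
    )


@dataclass
class ExpressionSimConfig:
    n_genes: int = 50
    n_tumor: int = 20
    n_normal_same_tissue: int = 30
    n_normal_other: int = 10
    tissue: str = "colon"
    other_tissue: str = "lung"
    normal_mean: float = 100.0
    normal_sd: float = 10.0
    shifts: dict = field(default_factory=dict)  # (gene_idx, tumor_idx) -> multiple of sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normal_sd <= 0:
            raise ValueError("normal_sd must be positive")


def generate_expression_with_normals(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Gaussian expression with designated tumor cells shifted by k standard deviations.

    Values are clipped at zero to respect the non-negativity of normalized
    expression; with the default mean/sd the clip is effectively inactive.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    tumor_ids = [f"T{j:03d}" for j in range(config.n_tumor)]
    normal_ids = [f"N{j:03d}" for j in range(config.n_normal_same_tissue)]
    other_ids = [f"O{j:03d}" for j in range(config.n_normal_other)]
    samples = tumor_ids + normal_ids + other_ids

    values = rng.normal(config.normal_mean, config.normal_sd,
                        size=(config.n_genes, len(samples)))
    for (gi, tj), k_sd in config.shifts.items():
        values[gi, tj] += k_sd * config.normal_sd
    values = np.clip(values, 0.0, None)

    meta = pd.DataFrame({
        "sample_id": samples,
        "is_tumor": [True] * len(tumor_ids) + [False] * (len(normal_ids) + len(other_ids)),
        "tissue": ([config.tissue] * (len(tumor_ids) + len(normal_ids))
                   + [config.other_tissue] * len(other_ids)),
    }).set_index("sample_id")
    return ExpressionMatrix(genes, samples, values, meta)


def small_fixture() -> SyntheticCohort:
    """Deterministic 20-gene x 30-sample cohort with 3 planted SL pairs.

    Loss rates are inflated well above the genome-wide defaults so every
    fraction has non-empty denominators at n = 30; co-loss is fully suppressed
    (rho = 0), so each planted pair's co-loss fractions are exactly zero.
    """
    config = SyntheticCohortConfig(
        n_genes=20,
        n_samples=30,
        n_chromosomes=6,
        cnv_probs={-2: 0.15, -1: 0.20, 0: 0.55, 1: 0.07, 2: 0.03},
        expr_probs={-1: 0.20, 0: 0.60, 1: 0.20},
        n_sl_pairs=3,
        n_nonsl_pairs=10,
        rho=0.0,
        kappa=3.0,
        n_heavy_deletion_samples=0,
        seed=20150501,
    )
    return generate_cohort(config)
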