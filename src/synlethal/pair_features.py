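"""Per-pair co-loss and up-down compensation fractions.

Each fraction is a conditional frequency over tumor samples: the number of
samples showing the event of interest divided by the number of samples in
which the pair sits in the event's "at-risk" status set. Using CNV codes
(-2 homozygous deletion, -1 heterozygous deletion, 0 normal, 1 duplication,
2 amplification) and expression-status codes (-1 under, 0 normal, 1 over):

=========  ==================  ============================================
fraction   numerator           denominator (symmetric in A and B)
=========  ==================  ============================================
f1 homCL   (-2, -2)            A=-2 and B in {0,-2}, or vice versa
f2 hetCL   (-1, -1)            A=-1 and B in {0,-1}, or vice versa
f3 mixCL   (-2,-1) or (-1,-2)  A=-2 and B in {0,-1}, or vice versa
f4         (-1, -1) on expr    A=-1 and B in {0,-1}, or vice versa
f5         (-1,1) or (1,-1)    at least one gene under-expressed (-1)
f6 (opt)   one in {1,2},       at least one gene in {-1,-2}
           other in {-1,-2}
=========  ==================  ============================================

f1 excludes hyper-deleted samples (more than ``high_deletion_threshold``
genes homozygously lost), which would otherwise inflate co-loss for any pair.
A fraction with an empty denominator is reported as missing (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CNVMatrix,
    ExpressionStatusMatrix,
    GeneAnnotation,
    LabeledPairSet,
    canonical_pair,
)

logger = logging.getLogger(__name__)


def _isin(x: np.ndarray, codes) -> np.ndarray:
    out = np.zeros(x.shape, dtype=bool)
    for c in codes:
        out |= x == c
    return out


@dataclass(frozen=True)
class EventSpec:
    """Numerator/denominator status sets defining one fraction."""

    name: str
    source: str  # "cnv" or "expression"
    numerator: frozenset  # set of (status_a, status_b) tuples
    denominator: frozenset

    def __post_init__(self) -> None:
        if not self.numerator <= self.denominator:
            raise ValueError(f"{self.name}: numerator states must lie in denominator")

    def numerator_mask(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self._mask(a, b, self.numerator)

    def denominator_mask(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self._mask(a, b, self.denominator)

    @staticmethod
    def _mask(a, b, cells) -> np.ndarray:
        out = np.zeros(a.shape, dtype=bool)
        for sa, sb in cells:
            out |= (a == sa) & (b == sb)
        return out


def _sym(cells) -> frozenset:
    return frozenset(cells) | frozenset((b, a) for a, b in cells)


EVENTS: dict[str, EventSpec] = {
    "homCL": EventSpec(
        "homCL", "cnv",
        numerator=_sym({(-2, -2)}),
        denominator=_sym({(-2, 0), (-2, -2)}),
    ),
    "hetCL": EventSpec(
        "hetCL", "cnv",
        numerator=_sym({(-1, -1)}),
        denominator=_sym({(-1, 0), (-1, -1)}),
    ),
    # the mixed co-loss denominator pairs a homozygous deletion with Z={0,-1};
    # (-2,-2) samples are deliberately outside it
    "mixCL": EventSpec(
        "mixCL", "cnv",
        numerator=_sym({(-2, -1)}),
        denominator=_sym({(-2, 0), (-2, -1)}),
    ),
    "co_under": EventSpec(
        "co_under", "expression",
        numerator=_sym({(-1, -1)}),
        denominator=_sym({(-1, 0), (-1, -1)}),
    ),
    "expr_updown": EventSpec(
        "expr_updown", "expression",
        numerator=_sym({(-1, 1)}),
        denominator=_sym({(-1, -1), (-1, 0), (-1, 1)}),
    ),
    "cnv_updown": EventSpec(
        "cnv_updown", "cnv",
        numerator=_sym({(-1, 1), (-1, 2), (-2, 1), (-2, 2)}),
        denominator=_sym({
            (a, b) for a in (-2, -1) for b in (-2, -1, 0, 1, 2)
        }),
    ),
}

FRACTION_EVENTS = {
    "f1": "homCL", "f2": "hetCL", "f3": "mixCL",
    "f4": "co_under", "f5": "expr_updown", "f6": "cnv_updown",
}
FRACTION_COLUMNS = ["f1", "f2", "f3", "f4", "f5"]


@dataclass
class FeatureConfig:
    high_deletion_threshold: int = 2000
    # the hyper-deleted-sample filter applies to f1 only by default
    filter_all_cnv_fractions: bool = False
    include_genomic_updown: bool = False


def flag_high_deletion_samples(cnv: CNVMatrix, threshold: int = 2000) -> set[str]:
    """Samples with homozygous deletions of strictly more than ``threshold`` genes."""
    counts = (cnv.status == -2).sum(axis=0)
    return {s for s, c in zip(cnv.sample_ids, counts) if c > threshold}


def _sample_mask(matrix, excluded_samples) -> np.ndarray:
    excluded = set(excluded_samples or ())
    return np.array([s not in excluded for s in matrix.sample_ids], dtype=bool)


def event_counts(
    matrix: CNVMatrix | ExpressionStatusMatrix,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    event: EventSpec,
    excluded_samples=(),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (n_event, n_t) for many pairs given matrix row indices."""
    keep = _sample_mask(matrix, excluded_samples)
    a = matrix.status[np.asarray(idx_a, dtype=np.intp)][:, keep]
    b = matrix.status[np.asarray(idx_b, dtype=np.intp)][:, keep]
    n_event = event.numerator_mask(a, b).sum(axis=1)
    n_t = event.denominator_mask(a, b).sum(axis=1)
    return n_event, n_t


def coloss_fraction(
    pair: tuple[str, str],
    matrix: CNVMatrix | ExpressionStatusMatrix,
    event: EventSpec | str,
    excluded_samples=(),
) -> tuple[int, int, float]:
    """(n_event, n_t, fraction) for one pair; fraction is NaN when n_t = 0."""
    if isinstance(event, str):
        event = EVENTS[event]
    ia = matrix.gene_indices([pair[0]])
    ib = matrix.gene_indices([pair[1]])
    n_event, n_t = event_counts(matrix, ia, ib, event, excluded_samples)
    n_event, n_t = int(n_event[0]), int(n_t[0])
    frac = n_event / n_t if n_t else float("nan")
    return n_event, n_t, frac


def updown_fraction(
    pair: tuple[str, str],
    matrix: ExpressionStatusMatrix | CNVMatrix,
    variant: str = "expression",
    excluded_samples=(),
) -> tuple[int, int, float]:
    """Compensation fraction: one gene up while the partner is down.

    ``variant="expression"`` counts over-expression against under-expression
    on the status matrix; ``variant="genomic"`` counts duplication or
    amplification against deletion on the CNV matrix.
    """
    event = {"expression": "expr_updown", "genomic": "cnv_updown"}[variant]
    return coloss_fraction(pair, matrix, event, excluded_samples)


def single_loss_rate(
    gene: str,
    matrix: CNVMatrix | ExpressionStatusMatrix,
    code: int,
    excluded_samples=(),
) -> float:
    """Fraction of non-excluded samples in which the gene has the given status."""
    keep = _sample_mask(matrix, excluded_samples)
    row = matrix.gene_row(gene)[keep]
    return float((row == code).mean()) if row.size else float("nan")


def exclude_same_chromosome(pairs, annotation: GeneAnnotation):
    """Keep only pairs whose two genes lie on different chromosomes.

    Pairs with an unannotated gene are dropped and logged, not silently kept.
    Accepts a :class:`LabeledPairSet` (returned filtered) or a plain list of
    pair tuples (returned as a list).
    """
    if isinstance(pairs, LabeledPairSet):
        df = pairs.pairs
        keep, dropped_unannot, dropped_same = [], 0, 0
        for a, b in zip(df["gene_a"], df["gene_b"]):
            ca, cb = annotation.chromosome(a), annotation.chromosome(b)
            if ca is None or cb is None:
                dropped_unannot += 1
                keep.append(False)
            elif ca == cb:
                dropped_same += 1
                keep.append(False)
            else:
                keep.append(True)
        if dropped_unannot:
            logger.info("dropped %d pair(s) with unannotated genes", dropped_unannot)
        logger.info("dropped %d same-chromosome pair(s), kept %d",
                    dropped_same, int(np.sum(keep)))
        return LabeledPairSet(df[np.asarray(keep, dtype=bool)].reset_index(drop=True))
    out = []
    n_unannot = 0
    for a, b in pairs:
        ca, cb = annotation.chromosome(a), annotation.chromosome(b)
        if ca is None or cb is None:
            n_unannot += 1
        elif ca != cb:
            out.append((a, b))
    if n_unannot:
        logger.info("dropped %d pair(s) with unannotated genes", n_unannot)
    return out


def build_feature_table(
    pairs,
    cnv: CNVMatrix,
    expr_status: ExpressionStatusMatrix,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Fraction features for a list of (already chromosome-filtered) pairs.

    Returns one row per canonical pair with columns ``gene_a, gene_b,
    f1..f5[, f6]`` plus ``n_<event>`` / ``nt_<event>`` provenance counts.
    Pairs with a gene absent from either matrix are dropped with a log entry;
    fractions with empty denominators are NaN.
    """
    canon = sorted({canonical_pair(a, b) for a, b in pairs})
    usable, dropped = [], 0
    for a, b in canon:
        if a in cnv and b in cnv and a in expr_status and b in expr_status:
            usable.append((a, b))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d pair(s) with genes absent from a matrix", dropped)
    if not usable:
        cols = ["gene_a", "gene_b"] + list(FRACTION_COLUMNS)
        if config.include_genomic_updown:
            cols.append("f6")
        return pd.DataFrame(columns=cols)

    genes_a = [a for a, _ in usable]
    genes_b = [b for _, b in usable]
    high_del = flag_high_deletion_samples(cnv, config.high_deletion_threshold)
    out = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})

    fractions = list(FRACTION_COLUMNS) + (["f6"] if config.include_genomic_updown else [])
    for frac in fractions:
        event = EVENTS[FRACTION_EVENTS[frac]]
        matrix = cnv if event.source == "cnv" else expr_status
        if frac == "f1" or (config.filter_all_cnv_fractions and event.source == "cnv"):
            excluded = high_del
        else:
            excluded = ()
        ia = matrix.gene_indices(genes_a)
        ib = matrix.gene_indices(genes_b)
        n_event, n_t = event_counts(matrix, ia, ib, event, excluded)
        with np.errstate(invalid="ignore"):
            out[frac] = np.where(n_t > 0, n_event / np.maximum(n_t, 1), np.nan)
        out[f"n_{event.name}"] = n_event
        out[f"nt_{event.name}"] = n_t
    return out
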