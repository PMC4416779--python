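"""Call per-gene over/under-expression status in tumors against normal references.

For each tumor sample, every gene's expression is compared with a reference
panel of normal samples: same-tissue normals when at least
``min_same_tissue_normals`` of them exist, otherwise all normals. The z-score
(tumor value minus reference mean, over the reference sample standard
deviation) is converted to a two-sided normal-tail p-value, Benjamini-Hochberg
adjusted across genes within the tumor sample, and thresholded at
``alpha`` (default 0.05): status is sign(z) when the adjusted p passes, 0
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, ExpressionStatusMatrix

logger = logging.getLogger(__name__)


@dataclass
class StatusCallConfig:
    min_same_tissue_normals: int = 25
    alpha: float = 0.05
    bh_scope: str = "per_sample"  # or "global"

    def __post_init__(self) -> None:
        if self.min_same_tissue_normals < 2:
            raise ValueError("min_same_tissue_normals must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bh_scope not in ("per_sample", "global"):
            raise ValueError("bh_scope must be 'per_sample' or 'global'")


def select_normal_reference(
    tumor_tissue: str,
    sample_meta,
    config: StatusCallConfig = StatusCallConfig(),
) -> list[str]:
    """Pick the normal reference panel for tumors of a given tissue.

    Same-tissue normals when their count reaches ``min_same_tissue_normals``,
    else every normal sample regardless of tissue.
    """
    normals = sample_meta[~sample_meta["is_tumor"].astype(bool)]
    if len(normals) == 0:
        raise ValueError("no normal reference: zero normal samples available")
    same = normals[normals["tissue"] == tumor_tissue]
    if len(same) >= config.min_same_tissue_normals:
        return list(same.index)
    return list(normals.index)


def compute_z_and_p(tumor_value: float, reference_values) -> tuple[float, float]:
    """Z-score of one tumor value against a normal reference, with its p-value.

    Returns ``(z, p)`` where p is the two-sided standard-normal tail
    probability. A constant reference (sd = 0) yields ``(nan, 1.0)``.
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size < 2:
        raise ValueError("reference must contain at least 2 values")
    sd = ref.std(ddof=1)
    if sd == 0:
        return (float("nan"), 1.0)
    z = (tumor_value - ref.mean()) / sd
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_status_matrix(
    expr: ExpressionMatrix, config: StatusCallConfig = StatusCallConfig()
) -> ExpressionStatusMatrix:
    """Ternary expression-status calls for every (gene, tumor sample) cell.

    Normal samples are consumed as references only; the output sample set is
    exactly the tumor samples.
    """
    meta = expr.sample_meta
    tumors = expr.tumor_samples
    if not tumors:
        raise ValueError("no tumor samples in expression matrix")
    col = {s: j for j, s in enumerate(expr.sample_ids)}

    n_genes = len(expr.gene_ids)
    zmat = np.full((n_genes, len(tumors)), np.nan)
    pmat = np.ones((n_genes, len(tumors)))

    tissues = meta.loc[tumors, "tissue"]
    for tissue in tissues.unique():
        ref_ids = select_normal_reference(tissue, meta, config)
        ref = expr.values[:, [col[s] for s in ref_ids]]
        mean = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning(
                "%d gene(s) have a constant normal reference for tissue %r; "
                "their status is forced to 0", int(degenerate.sum()), tissue)
        cols = [j for j, s in enumerate(tumors) if tissues.iloc[j] == tissue]
        vals = expr.values[:, [col[tumors[j]] for j in cols]]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - mean[:, None]) / sd[:, None]
        z[degenerate, :] = np.nan
        p = 2.0 * stats.norm.sf(np.abs(z))
        p[degenerate, :] = 1.0
        zmat[:, cols] = z
        pmat[:, cols] = p

    if config.bh_scope == "global":
        padj = bh_adjust(pmat.ravel()).reshape(pmat.shape)
    else:
        padj = np.column_stack([bh_adjust(pmat[:, j]) for j in range(pmat.shape[1])])

    status = np.zeros_like(pmat, dtype=np.int8)
    significant = (padj <= config.alpha) & ~np.isnan(zmat)
    status[significant] = np.sign(zmat[significant]).astype(np.int8)
    return ExpressionStatusMatrix(list(expr.gene_ids), list(tumors), status)
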