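"""Readers, writers and validated in-memory containers for the pipeline's tables.

All matrices travel as tab-separated text: first column header ``gene_id``,
remaining headers sample ids. Copy-number status uses the GISTIC-style codes
-2 (homozygous deletion), -1 (heterozygous deletion), 0 (normal copy),
1 (duplication), 2 (amplification); expression status uses -1 (under-expressed),
0 (normal), 1 (over-expressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CNV_CODES = frozenset({-2, -1, 0, 1, 2})
EXPR_STATUS_CODES = frozenset({-1, 0, 1})
LABELS = ("SL", "nonSL")


class FormatError(ValueError):
    """Raised when an input table violates its dialect or value constraints."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class CNVMatrix:
    """Genes x samples integer copy-number status matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    status: np.ndarray  # (n_genes, n_samples), int

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"status shape {self.status.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = ~np.isin(self.status, list(CNV_CODES))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"CNV status {self.status[g, s]} outside {{-2..2}} "
                f"at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.status[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} absent from CNV matrix") from None

    def gene_indices(self, gene_ids) -> np.ndarray:
        try:
            return np.array([self._gene_index[g] for g in gene_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from CNV matrix") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index


@dataclass
class ExpressionStatusMatrix:
    """Genes x samples ternary over/normal/under expression-status matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("status shape inconsistent with ids")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = ~np.isin(self.status, list(EXPR_STATUS_CODES))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise FormatError(
                f"expression status {self.status[g, s]} outside {{-1,0,1}} "
                f"at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    gene_row = CNVMatrix.gene_row
    gene_indices = CNVMatrix.gene_indices
    __contains__ = CNVMatrix.__contains__


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with per-sample metadata.

    ``sample_meta`` is indexed by sample id and carries ``is_tumor`` (bool)
    and ``tissue`` (str).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("values shape inconsistent with ids")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        missing = [s for s in self.sample_ids if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing}")
        self.sample_meta = self.sample_meta.loc[self.sample_ids]

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.sample_ids if bool(self.sample_meta.at[s, "is_tumor"])]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.sample_ids if not bool(self.sample_meta.at[s, "is_tumor"])]


@dataclass
class GeneAnnotation:
    """Gene -> chromosome mapping; labels are normalized by stripping "chr"."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def normalize_chrom(label: str) -> str:
        label = str(label).strip()
        return label[3:] if label.lower().startswith("chr") else label

    def chromosome(self, gene_id: str) -> str | None:
        return self.chromosomes.get(gene_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.chromosomes

    def __len__(self) -> int:
        return len(self.chromosomes)


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Canonical unordered form: the two gene ids in lexicographic order."""
    if gene_a == gene_b:
        raise FormatError(f"self-pair not allowed: ({gene_a!r}, {gene_b!r})")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass
class LabeledPairSet:
    """Canonicalized, deduplicated unordered gene pairs with SL / nonSL labels."""

    pairs: pd.DataFrame  # columns gene_a, gene_b, label

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        expected = ["gene_a", "gene_b", "label"]
        if list(df.columns[:3]) != expected:
            raise FormatError(f"pair table needs columns {expected}")
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise FormatError(f"unknown label token(s): {sorted(bad)}; expected {LABELS}")
        canon = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
        df[["gene_a", "gene_b"]] = pd.DataFrame(canon, index=df.index)
        df = df.drop_duplicates()
        conflicts = df.duplicated(subset=["gene_a", "gene_b"], keep=False)
        if conflicts.any():
            pair = df.loc[conflicts, ["gene_a", "gene_b"]].iloc[0].tolist()
            raise FormatError(f"conflicting labels for pair {tuple(pair)}")
        self.pairs = df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)

    @property
    def n_positive(self) -> int:
        return int((self.pairs["label"] == "SL").sum())

    @property
    def n_negative(self) -> int:
        return int((self.pairs["label"] == "nonSL").sum())

    def genes(self, label: str | None = None) -> list[str]:
        df = self.pairs if label is None else self.pairs[self.pairs["label"] == label]
        return sorted(set(df["gene_a"]) | set(df["gene_b"]))

    def __len__(self) -> int:
        return len(self.pairs)


def _read_gene_by_sample(path) -> tuple[list[str], list[str], pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column header must be 'gene_id', got {df.columns[0]!r}")
    genes = df.iloc[:, 0].astype(str).tolist()
    samples = [str(c) for c in df.columns[1:]]
    return genes, samples, df.iloc[:, 1:]


def read_cnv_matrix(path) -> CNVMatrix:
    """Read a genes x samples CNV status TSV into a validated :class:`CNVMatrix`."""
    genes, samples, body = _read_gene_by_sample(path)
    values = body.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cell in CNV matrix")
    if np.any(values != np.round(values)):
        raise FormatError(f"{path}: non-integer CNV status value")
    return CNVMatrix(genes, samples, values.astype(np.int8))


def read_expression_status_matrix(path) -> ExpressionStatusMatrix:
    """Read a precomputed -1/0/1 expression-status TSV."""
    genes, samples, body = _read_gene_by_sample(path)
    values = body.to_numpy()
    if np.any(values != np.round(values)):
        raise FormatError(f"{path}: non-integer expression status value")
    return ExpressionStatusMatrix(genes, samples, values.astype(np.int8))


def read_expression_matrix(path, meta_path) -> ExpressionMatrix:
    """Read a normalized expression TSV plus its sample metadata TSV.

    The metadata file has columns ``sample_id``, ``is_tumor`` (0/1 or
    true/false) and ``tissue``.
    """
    genes, samples, body = _read_gene_by_sample(path)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "tissue": str})
    need = {"sample_id", "is_tumor", "tissue"}
    if not need.issubset(meta.columns):
        raise FormatError(f"{meta_path}: metadata needs columns {sorted(need)}")
    meta["is_tumor"] = (
        meta["is_tumor"].astype(str).str.lower().map(
            {"1": True, "0": False, "true": True, "false": False}
        )
    )
    if meta["is_tumor"].isna().any():
        raise FormatError(f"{meta_path}: is_tumor must be 0/1 or true/false")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(genes, samples, body.to_numpy(dtype=float), meta)


def write_matrix(matrix: CNVMatrix | ExpressionStatusMatrix, path) -> None:
    df = pd.DataFrame(matrix.status, index=pd.Index(matrix.gene_ids, name="gene_id"),
                      columns=matrix.sample_ids)
    df.to_csv(path, sep="\t")


def write_expression_matrix(expr: ExpressionMatrix, path, meta_path) -> None:
    df = pd.DataFrame(expr.values, index=pd.Index(expr.gene_ids, name="gene_id"),
                      columns=expr.sample_ids)
    df.to_csv(path, sep="\t")
    meta = expr.sample_meta.reset_index()
    meta.columns = ["sample_id", *meta.columns[1:]]
    meta["is_tumor"] = meta["is_tumor"].astype(int)
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a two-column gene_id, chromosome TSV; an empty file is a valid empty map."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        return GeneAnnotation({})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: annotation needs gene_id and chromosome columns")
    mapping: dict[str, str] = {}
    for gene, chrom in zip(df.iloc[:, 0], df.iloc[:, 1]):
        chrom = GeneAnnotation.normalize_chrom(chrom)
        if gene in mapping and mapping[gene] != chrom:
            raise FormatError(
                f"{path}: gene {gene!r} annotated on both {mapping[gene]!r} and {chrom!r}"
            )
        mapping[str(gene)] = chrom
    return GeneAnnotation(mapping)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    pd.DataFrame(
        sorted(annotation.chromosomes.items()), columns=["gene_id", "chromosome"]
    ).to_csv(path, sep="\t", index=False)


def read_pair_labels(path) -> LabeledPairSet:
    """Read a gene_a, gene_b, label TSV into a canonical :class:`LabeledPairSet`."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no data rows") from None
    need = ["gene_a", "gene_b", "label"]
    if list(df.columns[:3]) != need:
        raise FormatError(f"{path}: pair list needs columns {need}")
    return LabeledPairSet(df[need])


def write_pair_labels(pairs: LabeledPairSet, path) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)


@dataclass
class PredictionTable:
    """Per-pair SL probability and thresholded call."""

    table: pd.DataFrame  # gene_a, gene_b, probability, call
    threshold: float

    def __post_init__(self) -> None:
        df = self.table
        need = ["gene_a", "gene_b", "probability", "call"]
        if list(df.columns[:4]) != need:
            raise FormatError(f"prediction table needs columns {need}")
        p = df["probability"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise FormatError("probability outside [0, 1]")
        expected = np.where(p >= self.threshold, "SL", "nonSL")
        if not (df["call"].to_numpy() == expected).all():
            raise FormatError("call column inconsistent with probability >= threshold")

    @classmethod
    def from_probabilities(cls, gene_a, gene_b, probability, threshold: float) -> "PredictionTable":
        p = np.asarray(probability, dtype=float)
        df = pd.DataFrame({
            "gene_a": list(gene_a),
            "gene_b": list(gene_b),
            "probability": p,
            "call": np.where(p >= threshold, "SL", "nonSL"),
        })
        return cls(df, threshold)

    def __len__(self) -> int:
        return len(self.table)


def write_predictions(preds: PredictionTable, path) -> None:
    """Write predictions: descending probability, lexicographic tie-break, 6 decimals."""
    df = preds.table.copy()
    df["probability"] = df["probability"].astype(float).round(6)
    df = df.sort_values(
        ["probability", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path, threshold: float) -> PredictionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return PredictionTable(df, threshold)
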