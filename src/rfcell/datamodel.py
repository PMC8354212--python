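"""Core containers and text I/O for expression matrices, labels and gene sets.

The internal orientation is fixed: rows are cells, columns are genes.
Values are assumed to be already-normalized nonnegative expression units
(CPM/TPM/RPKM/FPKM); no normalization from raw counts is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells x genes matrix of nonnegative normalized expression values.

    Parameters
    ----------
    values : (m, n) float array, finite and >= 0.
    cell_ids : m unique row identifiers.
    gene_ids : n unique column identifiers.
    unit : free-text tag for the expression unit (e.g. ``"TPM"``).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        cell_ids = np.asarray(self.cell_ids, dtype=object)
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        if values.ndim != 2:
            raise ValidationError(f"expected 2-D matrix, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value {values[i, j]} at "
                f"cell {cell_ids[i]!r}, gene {gene_ids[j]!r}"
            )
        if values.shape != (len(cell_ids), len(gene_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        _check_unique(cell_ids, "cell")
        _check_unique(gene_ids, "gene")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "gene_ids", gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the matrix restricted to ``gene_ids`` (in the given order)."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise ValidationError(f"unknown gene id: {exc.args[0]!r}") from None
        return ExpressionMatrix(
            self.values[:, cols],
            self.cell_ids,
            np.asarray(list(gene_ids), dtype=object),
            self.unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class LabelVector:
    """Per-cell categorical labels aligned to an expression matrix's cells."""

    labels: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.size < 1:
            raise ValidationError("label vector must be non-empty")
        object.__setattr__(self, "labels", labels)
        if self.cell_ids is not None:
            cell_ids = np.asarray(self.cell_ids, dtype=object)
            if len(cell_ids) != len(labels):
                raise ValidationError("cell_ids length does not match labels")
            object.__setattr__(self, "cell_ids", cell_ids)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_distinct(self) -> int:
        return len(set(self.labels))


@dataclass(frozen=True)
class GeneSet:
    """An ordered selection of genes with aligned scores (e.g. MDA)."""

    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        gene_ids = np.asarray(self.gene_ids, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if len(gene_ids) != len(scores):
            raise ValidationError("gene_ids and scores must be aligned")
        _check_unique(gene_ids, "gene")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    format: str = "csv",
    orientation: str = "cells_by_genes",
    unit: str = "",
) -> ExpressionMatrix:
    """Load an expression matrix from delimited text or MatrixMarket.

    For ``csv``/``tsv``: the header row holds gene ids and the first column
    cell ids (or the transpose under ``orientation="genes_by_cells"``).
    For ``mtx``: companion files ``genes.txt`` and ``cells.txt`` next to the
    matrix hold one identifier per line; the coordinate matrix is
    genes x cells unless ``orientation`` says otherwise, following the
    common 10x-style layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed {format} file {path}: {exc}") from exc
        non_numeric = frame.columns[
            [not np.issubdtype(d, np.number) for d in frame.dtypes]
        ]
        if len(non_numeric):
            raise ValidationError(
                f"non-numeric column {non_numeric[0]!r} in {path}"
            )
        values = frame.to_numpy(dtype=float)
        row_ids = frame.index.to_numpy(dtype=object)
        col_ids = frame.columns.to_numpy(dtype=object)
    elif format == "mtx":
        genes_file = path.parent / "genes.txt"
        cells_file = path.parent / "cells.txt"
        for companion in (genes_file, cells_file):
            if not companion.exists():
                raise FileNotFoundError(companion)
        mat = mmread(path)
        values = np.asarray(mat.toarray() if hasattr(mat, "toarray") else mat,
                            dtype=float)
        gene_ids = np.loadtxt(genes_file, dtype=str, ndmin=1).astype(object)
        cell_ids = np.loadtxt(cells_file, dtype=str, ndmin=1).astype(object)
        # MTX convention here: rows are genes unless orientation overrides.
        if orientation == "genes_by_cells":
            row_ids, col_ids = gene_ids, cell_ids
        else:
            row_ids, col_ids = cell_ids, gene_ids
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, unit=unit)


def write_expression(x: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    """Write cells x genes values as delimited text with full float precision."""
    x.to_frame().to_csv(Path(path), sep=sep, float_format="%.17g")


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column (cell_id, label) or single-column label file."""
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[1] < 1:
        raise ValidationError(f"label file {path} has no label column")
    return LabelVector(
        frame.iloc[:, 0].to_numpy(dtype=object),
        frame.index.to_numpy(dtype=object),
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    ids = (
        labels.cell_ids
        if labels.cell_ids is not None
        else np.array([f"cell_{i}" for i in range(len(labels))], dtype=object)
    )
    pd.DataFrame({"label": labels.labels}, index=pd.Index(ids, name="cell_id")).to_csv(path)


def log_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log(1 + v); the unit tag is suffixed ``"+log1p"``."""
    return replace(x, values=np.log1p(x.values), unit=x.unit + "+log1p")


def sorted_gene_set(gene_ids: Sequence[str], scores: Sequence[float]) -> GeneSet:
    """Order genes by descending score, breaking ties by gene id."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((gene_ids, -scores))
    return GeneSet(gene_ids[order], scores[order])


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    """Write a gene set as two-column TSV (gene_id, score), best first."""
    ordered = sorted_gene_set(gs.gene_ids, gs.scores)
    with open(path, "w") as fh:
        fh.write("gene_id\tscore\n")
        for g, s in zip(ordered.gene_ids, ordered.scores):
            fh.write(f"{g}\t{s:.17g}\n")


def read_gene_set(path: str | Path) -> GeneSet:
    frame = pd.read_csv(path, sep="\t")
    return GeneSet(
        frame["gene_id"].to_numpy(dtype=object),
        frame["score"].to_numpy(dtype=float),
    )


def min_cells_filter(x: ExpressionMatrix, min_cells: int) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in fewer than ``min_cells`` cells.

    Off by default in every pipeline entry point; provided as an explicit,
    optional preprocessing step.
    """
    keep = (x.values > 0).sum(axis=0) >= min_cells
    if keep.all():
        return x
    if not keep.any():
        warnings.warn("min_cells_filter removed every gene", stacklevel=2)
    return ExpressionMatrix(
        x.values[:, keep], x.cell_ids, x.gene_ids[keep], x.unit
    )
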