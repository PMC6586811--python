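"""Reading, validating and writing labeled gene-expression tables.

The on-disk dialect is one sample per row: a header row of unique gene
identifiers plus one designated label column (default ``"class"``),
comma- or tab-delimited, plain decimal numbers, no quoting. This matches
the small-n / large-p shape of microarray studies, where a matrix of a
few dozen to a few hundred samples over thousands of genes is the unit
of analysis.

Missing or non-numeric expression values are rejected at load time, not
imputed: no imputation rule is defined for this pipeline and silently
inventing one would change downstream gene weights.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "FormatError",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "write_selection_report",
    "read_selection_report",
]


class FormatError(ValueError):
    """The file cannot be parsed as a labeled expression table."""


class ValidationError(ValueError):
    """The parsed table violates an ExpressionDataset invariant."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A labeled samples-by-genes expression matrix.

    Attributes
    ----------
    values : numpy.ndarray
        ``(n_samples, n_genes)`` float64 matrix of expression values in
        arbitrary units; every entry finite.
    gene_ids : tuple of str
        Unique gene identifiers, one per column.
    sample_ids : tuple of str
        Unique sample identifiers, one per row.
    labels : tuple of str
        One class label per sample; at least two distinct classes.
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple
    labels: tuple

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, p = values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValidationError("need at least 1 gene")
        if len(self.gene_ids) != p:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {p} matrix columns"
            )
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError(
                "sample ids and labels must both match the matrix row count"
            )
        if len(set(self.gene_ids)) != p:
            dupes = [g for g, c in Counter(self.gene_ids).items() if c > 1]
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if len(set(self.labels)) < 2:
            raise ValidationError(
                "dataset must contain at least 2 distinct classes, "
                f"found only {set(self.labels)}"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def class_set(self) -> tuple:
        """Distinct class labels, sorted."""
        return tuple(sorted(set(self.labels)))

    def class_priors(self) -> dict:
        """Fraction of all samples in each class, summing to 1."""
        counts = Counter(self.labels)
        n = self.n_samples
        return {c: counts[c] / n for c in self.class_set}

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


def read_expression_table(path, label_column: str = "class",
                          delimiter: str = ",") -> ExpressionDataset:
    """Read a delimited samples-by-genes table with one label column.

    The gene axis is the one named by the header: a transposed file (genes
    as rows) fails loudly because the label column is absent from the
    header. Every non-label cell must parse as a finite real number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        try:
            header = next(csv.reader(fh, delimiter=delimiter))
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
    dupes = [h for h, c in Counter(header).items() if c > 1]
    if dupes:
        raise FormatError(f"{path}: duplicate column identifiers {dupes[:5]}")
    if header.count(label_column) != 1:
        raise FormatError(
            f"{path}: label column {label_column!r} not found in header — "
            "is the file transposed (genes as rows)?"
        )

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    labels = [s.strip() for s in df[label_column].tolist()]
    for i, lbl in enumerate(labels):
        if lbl == "":
            raise FormatError(f"{path}: missing class label at data row {i + 1}")

    gene_ids = [h for h in header if h != label_column]
    n = len(df)
    values = np.empty((n, len(gene_ids)), dtype=float)
    for j, g in enumerate(gene_ids):
        raw = df[g].to_numpy(dtype=object)
        try:
            # object->float via python float(): correctly rounded round-trip
            col = raw.astype(float)
        except (ValueError, TypeError):
            bad = next(i for i, cell in enumerate(raw)
                       if not _parses_as_float(cell))
            raise FormatError(
                f"{path}: non-numeric or missing expression value at data row "
                f"{bad + 1}, column {g!r} (cell {raw[bad]!r})"
            ) from None
        nonfinite = np.flatnonzero(~np.isfinite(col))
        if nonfinite.size:
            raise FormatError(
                f"{path}: non-finite expression value at data row "
                f"{nonfinite[0] + 1}, column {g!r} (cell {raw[nonfinite[0]]!r})"
            )
        values[:, j] = col

    sample_ids = tuple(f"s{i + 1}" for i in range(n))
    return ExpressionDataset(values, tuple(gene_ids), sample_ids, tuple(labels))


def _parses_as_float(cell) -> bool:
    try:
        float(cell)
        return True
    except (ValueError, TypeError):
        return False


def write_expression_table(dataset: ExpressionDataset, path,
                           label_column: str = "class",
                           delimiter: str = ",") -> None:
    """Write a dataset in the dialect :func:`read_expression_table` reads."""
    if label_column in dataset.gene_ids:
        raise FormatError(f"label column name {label_column!r} collides with a gene id")
    df = pd.DataFrame(dataset.values, columns=list(dataset.gene_ids))
    df[label_column] = list(dataset.labels)
    # %.17g keeps full float64 precision so write->read round-trips exactly
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def _weight_rank(weights: np.ndarray) -> np.ndarray:
    """1-based rank by descending weight, ties broken by ascending index."""
    order = np.lexsort((np.arange(weights.size), -weights))
    rank = np.empty(weights.size, dtype=int)
    rank[order] = np.arange(1, weights.size + 1)
    return rank


def write_selection_report(result, weights, out_dir) -> None:
    """Write a gene-weight table and a structured run summary.

    Produces ``weights.tsv`` (gene_id, weight, rank, selected) and
    ``summary.json`` (selected genes, CV accuracy, seed, full config,
    per-iteration history) under *out_dir*. A round-trip through
    :func:`read_selection_report` reproduces the selected set exactly.

    *result* must carry ``selected_genes``, ``cv_accuracy``, ``history``,
    ``config`` and ``seed``; *weights* must be the weight vector over the
    same gene universe the selection was made from.
    """
    gene_ids = list(weights.gene_ids)
    selected = list(result.selected_genes)
    unknown = sorted(set(selected) - set(gene_ids))
    if unknown:
        raise ValidationError(
            f"selection refers to genes absent from the weight vector: {unknown[:5]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    w = np.asarray(weights.weights, dtype=float)
    sel_set = set(selected)
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "weight": w,
            "rank": _weight_rank(w),
            "selected": [int(g in sel_set) for g in gene_ids],
        }
    )
    table.to_csv(out_dir / "weights.tsv", sep="\t", index=False)

    summary = {
        "selected_genes": selected,
        "cv_accuracy": float(result.cv_accuracy),
        "seed": result.seed,
        "config": result.config,
        "history": list(result.history),
        "relieff": {"m": weights.m, "k": weights.k, "seed": weights.seed},
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_selection_report(out_dir):
    """Read back a report written by :func:`write_selection_report`.

    Returns ``(summary_dict, weights_dataframe)``.
    """
    out_dir = Path(out_dir)
    with open(out_dir / "summary.json") as fh:
        summary = json.load(fh)
    table = pd.read_csv(out_dir / "weights.tsv", sep="\t")
    return summary, table
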