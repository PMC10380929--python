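"""Readers and writers for the flat-file dialects the tool consumes.

Expression matrices are TSV/CSV with a header row of gene (or probe) IDs and
sample IDs in the first column.  Labels are a two-column table
(sample_id, label in {0,1}) or a named column of the matrix.  Probe-gene
mappings are two-column TSV.  Known-gene lists are one ID per line with ``#``
comments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import ExpressionDataset

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_mapping",
    "read_gene_list",
    "read_expression_dataset",
]

DEFAULT_NA = ("", "NA")


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, na_values=DEFAULT_NA) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0,
        na_values=list(na_values), keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path), index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label table needs columns (sample_id, label)")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    bad = set(s.unique()) - {0, 1}
    if bad:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(bad)}")
    return s.astype(int)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "label": labels.to_numpy()}).to_csv(
        path, sep=_sep(path), index=False
    )


def read_mapping(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping table needs columns (probe_id, gene_id)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_gene_list(path: str | Path) -> list[str]:
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_expression_dataset(
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
    label_col: str | None = None,
) -> ExpressionDataset:
    """Load a matrix plus labels, either from a separate file or a column."""
    values = read_matrix(matrix_path)
    if label_col is not None:
        if label_col not in values.columns:
            raise ValueError(f"label column {label_col!r} not in matrix")
        labels = values[label_col].astype(int)
        values = values.drop(columns=[label_col])
    elif labels_path is not None:
        labels = read_labels(labels_path)
    else:
        raise ValueError("provide labels_path or label_col")
    return ExpressionDataset(values, labels)
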