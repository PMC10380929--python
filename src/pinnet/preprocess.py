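"""Expression-matrix preprocessing.

Mirrors the standard microarray preparation pipeline: per-probe mean
imputation, removal of low-variability probes by interquartile range (IQR),
collapse of multiple probes per gene by maximum IQR, per-gene min-max scaling
to [0, 1], and gene-space intersection of two datasets.

Matrices are pandas DataFrames with samples as rows and probes/genes as
columns.  Quartiles use linear interpolation between order statistics
(numpy/pandas default, "type 7"); IQR ties are broken by first-occurrence
column order so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "ExpressionDataset",
    "mean_impute",
    "iqr",
    "iqr_filter",
    "collapse_probes",
    "minmax_scale",
    "intersect_genes",
]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix in [0, 1] with binary labels.

    ``values``: DataFrame, samples as rows (index = sample IDs), genes as
    columns.  ``labels``: Series aligned to the row index, case = 1,
    control = 0.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()][0]
            raise ValueError(f"no label for sample {missing!r}")
        self.labels = self.labels.astype(np.int64)
        if not set(np.unique(self.labels)).issubset({0, 1}):
            raise ValueError("labels must be binary (0 = control, 1 = case)")

    def validate(self) -> None:
        """Check the scaled-matrix invariants: finite, within [0,1], both classes."""
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains missing values")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("expression values fall outside [0, 1]")
        if self.labels.nunique() < 2:
            raise ValueError("both classes must be present")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)

    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=np.int64)


def _check_matrix(m: pd.DataFrame) -> None:
    if m.columns.duplicated().any():
        dup = m.columns[m.columns.duplicated()][0]
        raise ValueError(f"duplicate probe/gene identifier: {dup!r}")
    if m.index.duplicated().any():
        dup = m.index[m.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples")


def mean_impute(m: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing entry by its probe's mean over observed samples.

    A probe with no observed value at all is an error (there is nothing to
    impute from).
    """
    _check_matrix(m)
    n_obs = m.notna().sum(axis=0)
    if (n_obs == 0).any():
        bad = n_obs.index[n_obs == 0][0]
        raise ValueError(f"probe {bad!r} has no observed values")
    return m.fillna(m.mean(axis=0))


def iqr(m: pd.DataFrame) -> pd.Series:
    """Per-column interquartile range (Q3 - Q1, linear interpolation)."""
    return m.quantile(0.75) - m.quantile(0.25)


def iqr_filter(m: pd.DataFrame, drop_fraction: float = 0.30) -> pd.DataFrame:
    """Keep the ceil((1 - drop_fraction) * P) probes with highest IQR.

    Survivors keep their original column order.  Ties at the cut are broken
    by first-occurrence order (earlier columns win).
    """
    _check_matrix(m)
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in [0, 1)")
    if m.isna().any().any():
        raise ValueError("matrix has missing values; run mean_impute first")
    n_keep = int(np.ceil((1.0 - drop_fraction) * m.shape[1]))
    # stable argsort on -IQR: equal IQRs keep input order
    order = np.argsort(-iqr(m).to_numpy(), kind="stable")[:n_keep]
    keep = np.zeros(m.shape[1], dtype=bool)
    keep[order] = True
    return m.loc[:, keep]


def collapse_probes(m: pd.DataFrame, mapping: pd.DataFrame | dict) -> pd.DataFrame:
    """Collapse probes to genes, keeping the max-IQR probe per gene verbatim.

    ``mapping`` is either a dict probe_id -> gene_id or a two-column
    DataFrame (probe_id, gene_id).  Unmapped probes are dropped.  IQR is
    recomputed on the input matrix; ties keep the first probe in input order.
    Output columns are gene IDs ordered by first appearance of a mapped probe.
    """
    _check_matrix(m)
    if isinstance(mapping, pd.DataFrame):
        if mapping.shape[1] < 2:
            raise ValueError("mapping table needs two columns (probe_id, gene_id)")
        mapping = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    probe_iqr = iqr(m)
    best: dict[str, str] = {}  # gene -> chosen probe
    order: list[str] = []
    for probe in m.columns:
        gene = mapping.get(probe)
        if gene is None:
            continue
        if gene not in best:
            best[gene] = probe
            order.append(gene)
        elif probe_iqr[probe] > probe_iqr[best[gene]]:
            best[gene] = probe
    if not best:
        raise ValueError("mapping covers none of the probes in the matrix")
    out = m.loc[:, [best[g] for g in order]]
    out.columns = order
    return out


@dataclass
class MinMaxParams:
    """Fitted per-gene min/max, for inspection and inverse transformation."""

    data_min: pd.Series
    data_max: pd.Series
    scaler: MinMaxScaler = field(repr=False)

    def inverse(self, scaled: pd.DataFrame) -> pd.DataFrame:
        inv = self.scaler.inverse_transform(scaled.to_numpy())
        return pd.DataFrame(inv, index=scaled.index, columns=scaled.columns)


def minmax_scale(
    d: pd.DataFrame,
    fit_on: str = "all",
    train_index=None,
    clip: bool = False,
) -> tuple[pd.DataFrame, MinMaxParams]:
    """Affine-map each gene to [0, 1].

    ``fit_on='all'`` fits min/max on the full matrix (dataset-level
    preprocessing); ``fit_on='train_only'`` fits on the rows in
    ``train_index``, in which case held-out values can fall outside [0, 1]
    unless ``clip`` is set.  Constant genes map to 0 by convention.
    """
    if d.isna().any().any():
        raise ValueError("matrix has missing values; impute first")
    if fit_on not in ("all", "train_only"):
        raise ValueError("fit_on must be 'all' or 'train_only'")
    scaler = MinMaxScaler()
    if fit_on == "all":
        scaler.fit(d.to_numpy())
    else:
        if train_index is None:
            raise ValueError("fit_on='train_only' requires train_index")
        scaler.fit(d.loc[train_index].to_numpy())
    scaled = scaler.transform(d.to_numpy())
    if clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    out = pd.DataFrame(scaled, index=d.index, columns=d.columns)
    params = MinMaxParams(
        data_min=pd.Series(scaler.data_min_, index=d.columns),
        data_max=pd.Series(scaler.data_max_, index=d.columns),
        scaler=scaler,
    )
    return out, params


def intersect_genes(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their common genes, sorted, same order."""
    common = sorted(set(a.columns) & set(b.columns))
    if not common:
        raise ValueError("the two datasets share no genes")
    return a.loc[:, common], b.loc[:, common]
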