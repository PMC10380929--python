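"""Gene-set collections and the pathway-gene mask matrix.

A pathway layer constrains each hidden unit to the member genes of one curated
gene set.  This module parses MSigDB-style GMT files, filters sets against the
expression gene universe, and builds the binary mask matrix ``M`` (pathways x
genes) together with the per-pathway normalization vector ``u`` that keeps
pathway-node magnitudes independent of set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pathway",
    "PathwayCollection",
    "MaskMatrix",
    "read_gmt",
    "write_gmt",
    "filter_pathways",
    "build_mask",
    "normalization_vector",
    "NORM_MODES",
]

NORM_MODES = ("none", "inverse", "inverse_sqrt")


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: tuple[str, ...]  # deduplicated, first-occurrence order

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")


@dataclass
class PathwayCollection:
    """Ordered collection of named gene sets with unique names."""

    entries: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.entries]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate pathway name: {dup!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> Pathway:
        return self.entries[i]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.entries:
            out.update(p.genes)
        return out


def _dedup(genes: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(genes))


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a tab-delimited GMT file (name, description, member genes...).

    Duplicate gene IDs within a line are dropped, keeping first occurrence.
    Gene identifiers are opaque strings matched exactly.
    """
    entries: list[Pathway] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = _dedup(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            entries.append(Pathway(name, desc, genes))
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, p.description, *p.genes]) + "\n")


def filter_pathways(
    collection: PathwayCollection,
    universe: Iterable[str],
    min_genes: int = 10,
) -> PathwayCollection:
    """Intersect each gene set with ``universe`` and drop sets smaller than
    ``min_genes`` after intersection.  Order is preserved."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    uni = set(universe)
    kept: list[Pathway] = []
    for p in collection:
        genes = tuple(g for g in p.genes if g in uni)
        if len(genes) >= min_genes:
            kept.append(Pathway(p.name, p.description, genes))
    if not kept:
        raise ValueError(
            f"no pathway retained at min_genes={min_genes}; "
            "try a smaller min_genes or check gene identifiers"
        )
    return PathwayCollection(kept)


@dataclass
class MaskMatrix:
    """Binary pathway x gene membership matrix with normalization vector.

    ``M[i, j] == 1`` iff gene ``j`` belongs to pathway ``i``.  ``u`` rescales
    each pathway node's pre-activation: 1 (no normalization), 1/size, or
    1/sqrt(size), where size is the pathway's row sum.
    """

    M: np.ndarray
    pathway_names: list[str]
    gene_ids: list[str]
    u: np.ndarray
    norm_mode: str = "inverse_sqrt"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2:
            raise ValueError("M must be 2-D")
        m, n = self.M.shape
        if len(self.pathway_names) != m or len(self.gene_ids) != n:
            raise ValueError("mask dimensions do not match name lists")
        if not np.isin(self.M, (0.0, 1.0)).all():
            raise ValueError("M must be binary")
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.shape != (m,) or not np.all(self.u > 0):
            raise ValueError("u must be a positive vector of length m")

    @property
    def n_pathways(self) -> int:
        return self.M.shape[0]

    @property
    def n_genes(self) -> int:
        return self.M.shape[1]

    @property
    def sizes(self) -> np.ndarray:
        """Number of member genes per pathway (row sums)."""
        return self.M.sum(axis=1)

    def with_norm_mode(self, mode: str) -> "MaskMatrix":
        return MaskMatrix(
            self.M, list(self.pathway_names), list(self.gene_ids),
            normalization_vector(self.M, mode), mode,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.M.astype(np.int64), index=self.pathway_names, columns=self.gene_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pathway")


def normalization_vector(M: np.ndarray, mode: str = "inverse_sqrt") -> np.ndarray:
    """Per-pathway normalization scalars from row sums.

    mode 'none' -> 1; 'inverse' -> 1/size; 'inverse_sqrt' -> 1/sqrt(size).
    """
    if mode not in NORM_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; choose from {NORM_MODES}")
    sizes = np.asarray(M, dtype=np.float64).sum(axis=1)
    if np.any(sizes < 1):
        bad = int(np.argmin(sizes))
        raise ValueError(f"pathway row {bad} has zero genes; filter the collection first")
    if mode == "none":
        return np.ones_like(sizes)
    if mode == "inverse":
        return 1.0 / sizes
    return 1.0 / np.sqrt(sizes)


def build_mask(
    collection: PathwayCollection,
    gene_order: Sequence[str],
    norm_mode: str = "inverse_sqrt",
) -> MaskMatrix:
    """Build the binary membership matrix in (collection order) x (gene_order).

    The collection must already be filtered against ``gene_order``'s gene set:
    a member gene absent from ``gene_order`` is a contract violation, not a
    silent drop.
    """
    if len(collection) == 0:
        raise ValueError("empty pathway collection")
    gene_index = {g: j for j, g in enumerate(gene_order)}
    if len(gene_index) != len(gene_order):
        raise ValueError("gene_order contains duplicates")
    M = np.zeros((len(collection), len(gene_order)), dtype=np.float64)
    for i, p in enumerate(collection):
        for g in p.genes:
            j = gene_index.get(g)
            if j is None:
                raise ValueError(
                    f"gene {g!r} of pathway {p.name!r} missing from gene_order; "
                    "run filter_pathways against this gene universe first"
                )
            M[i, j] = 1.0
    return MaskMatrix(
        M, collection.names, list(gene_order), normalization_vector(M, norm_mode), norm_mode
    )
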