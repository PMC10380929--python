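"""Synthetic expression data with differential signal planted in pathways.

The generator emulates the statistical shape the classifier expects: a
MinMax-scaled samples x genes matrix in [0, 1], class-imbalanced binary
labels, a GMT-style pathway collection with overlapping membership, and a
ground-truth list of signal genes whose case-group means are shifted.  Signal
genes live inside designated "signal pathways", so pathway-masked models can
exploit the prior while unmasked baselines cannot.

Baseline expression is Gaussian noise (optionally equicorrelated across genes
within a sample); the case-group mean shift is applied in pre-scaling units,
then each gene is min-max scaled to [0, 1].  Labels use a fixed case count
``round(case_fraction * n_samples)`` so both classes are always present and
stratification arithmetic is exact.  Every output is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .pathways import Pathway, PathwayCollection, write_gmt
from .preprocess import ExpressionDataset, minmax_scale

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_pathways",
    "generate_expression",
    "default_benchmark",
    "write_bundle",
    "DEFAULT_CONFIG",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 300
    case_fraction: float = 0.33
    n_genes: int = 1000
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 60)
    n_signal_pathways: int = 5
    n_signal_genes_per_pathway: int = 4
    effect_size: float = 1.5  # case-group mean shift, pre-scaling units
    noise_sd: float = 1.0
    background_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("max pathway size exceeds gene count")
        if self.n_signal_pathways > self.n_pathways:
            raise ValueError("more signal pathways than pathways")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.background_corr < 1.0):
            raise ValueError("background_corr must lie in [0, 1)")


DEFAULT_CONFIG = SimulationConfig()


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal."""

    signal_gene_ids: list[str]
    signal_pathway_names: list[str]
    effects: dict[str, float] = field(default_factory=dict)  # pre-scaling shift per gene

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["signal_gene_ids"], d["signal_pathway_names"], d.get("effects", {}))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_pathways(cfg: SimulationConfig) -> PathwayCollection:
    """Sample overlapping gene sets: sizes uniform in the configured range,
    members drawn without replacement within a set, freely shared across
    sets (as in real ontologies)."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "pathways"))
    genes = _gene_ids(cfg.n_genes)
    lo, hi = cfg.pathway_size_range
    entries = []
    width = max(3, len(str(cfg.n_pathways)))
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(cfg.n_genes, size=size, replace=False)
        entries.append(
            Pathway(
                f"PW{i + 1:0{width}d}",
                "synthetic pathway",
                tuple(genes[j] for j in sorted(members)),
            )
        )
    return PathwayCollection(entries)


def generate_expression(
    cfg: SimulationConfig, pathways: PathwayCollection
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Simulate the labelled expression matrix and record the planted truth.

    Signal genes are chosen without replacement across signal pathways so the
    truth list has exactly ``n_signal_pathways * n_signal_genes_per_pathway``
    distinct genes; a pathway whose unclaimed members run out is skipped in
    favor of the next one (config is validated to make this rare).
    """
    rng = np.random.default_rng(derive_seed(cfg.seed, "expression"))
    genes = _gene_ids(cfg.n_genes)
    gene_index = {g: j for j, g in enumerate(genes)}

    n_case = int(round(cfg.case_fraction * cfg.n_samples))
    if n_case < 1 or n_case >= cfg.n_samples:
        raise ValueError("case_fraction leaves an empty class")
    labels = np.zeros(cfg.n_samples, dtype=np.int64)
    labels[rng.choice(cfg.n_samples, size=n_case, replace=False)] = 1

    noise = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_genes))
    if cfg.background_corr > 0:
        shared = rng.normal(0.0, 1.0, size=(cfg.n_samples, 1))
        noise = (
            np.sqrt(cfg.background_corr) * shared
            + np.sqrt(1.0 - cfg.background_corr) * noise
        )
    X = cfg.noise_sd * noise

    # plant signal inside designated pathways
    order = rng.permutation(len(pathways))
    signal_pathways: list[str] = []
    signal_genes: list[str] = []
    claimed: set[str] = set()
    for idx in order:
        if len(signal_pathways) == cfg.n_signal_pathways:
            break
        pw = pathways[int(idx)]
        free = [g for g in pw.genes if g not in claimed]
        if len(free) < cfg.n_signal_genes_per_pathway:
            continue
        chosen = rng.choice(len(free), size=cfg.n_signal_genes_per_pathway, replace=False)
        picked = [free[int(c)] for c in sorted(chosen)]
        claimed.update(picked)
        signal_genes.extend(picked)
        signal_pathways.append(pw.name)
    if len(signal_pathways) < cfg.n_signal_pathways:
        raise ValueError("could not place the requested signal in distinct genes")

    if cfg.effect_size > 0:
        cols = [gene_index[g] for g in signal_genes]
        X[np.ix_(labels == 1, cols)] += cfg.effect_size

    values = pd.DataFrame(X, index=[f"S{i + 1:04d}" for i in range(cfg.n_samples)], columns=genes)
    scaled, _ = minmax_scale(values, fit_on="all")
    scaled = scaled.clip(0.0, 1.0)  # guard the [0,1] contract against fp round-off
    dataset = ExpressionDataset(scaled, pd.Series(labels, index=values.index))
    dataset.validate()
    truth = SyntheticTruth(
        signal_gene_ids=sorted(signal_genes),
        signal_pathway_names=signal_pathways,
        effects={g: cfg.effect_size for g in signal_genes},
    )
    return dataset, truth


def default_benchmark(
    seed: int = 0, **overrides
) -> tuple[ExpressionDataset, PathwayCollection, SyntheticTruth, SimulationConfig]:
    """Canonical benchmark: 300 samples (case fraction 0.33, mimicking an
    imbalanced cohort), 1000 genes, 50 pathways of 10-60 genes, 5 signal
    pathways x 4 signal genes (20 truth genes), effect size 1.5, unit noise."""
    cfg = SimulationConfig(seed=seed, **overrides)
    pathways = generate_pathways(cfg)
    dataset, truth = generate_expression(cfg, pathways)
    return dataset, pathways, truth, cfg


def write_bundle(
    out_dir: str | Path,
    dataset: ExpressionDataset,
    pathways: PathwayCollection,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write expr.tsv / labels.tsv / sets.gmt / truth.json into ``out_dir``."""
    from .io import write_labels, write_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out / "expr.tsv",
        "labels": out / "labels.tsv",
        "gmt": out / "sets.gmt",
        "truth": out / "truth.json",
    }
    write_matrix(dataset.values, paths["expr"])
    write_labels(dataset.labels, paths["labels"])
    write_gmt(pathways, paths["gmt"])
    truth.to_json(paths["truth"])
    return paths
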