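import numpy as np
import pandas as pd
import pytest

from pinnet import TrainOptions, default_benchmark
from pinnet.model import PINNet, PINNetConfig
from pinnet.pathways import MaskMatrix, build_mask, filter_pathways, normalization_vector


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark bundle (seed 7): dataset, mask, truth."""
    dataset, pathways, truth, cfg = default_benchmark(seed=7)
    collection = filter_pathways(pathways, dataset.gene_ids, min_genes=10)
    mask = build_mask(collection, dataset.gene_ids)
    return dataset, mask, truth, cfg


@pytest.fixture(scope="session")
def small_benchmark():
    """Scaled-down bundle for fast training tests."""
    dataset, pathways, truth, cfg = default_benchmark(
        seed=11, n_samples=160, n_genes=200, n_pathways=15,
        pathway_size_range=(10, 30), n_signal_pathways=3,
    )
    collection = filter_pathways(pathways, dataset.gene_ids, min_genes=10)
    mask = build_mask(collection, dataset.gene_ids)
    return dataset, mask, truth, cfg


@pytest.fixture()
def toy_mask():
    """3 genes, 2 pathways: P1={g1,g2}, P2={g2,g3}."""
    M = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
    return MaskMatrix(M, ["P1", "P2"], ["g1", "g2", "g3"],
                      normalization_vector(M, "inverse_sqrt"), "inverse_sqrt")


@pytest.fixture()
def toy_model(toy_mask):
    cfg = PINNetConfig(n_genes=3, n_pathways=2, n_fc_nodes=4, n_hidden=5, seed=123)
    return PINNet(cfg, toy_mask)


@pytest.fixture(scope="session")
def fast_opts():
    return TrainOptions(max_epochs=40)


def make_probe_frame(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{j}" for j in range(values.shape[1])]
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=samples, columns=probes)
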