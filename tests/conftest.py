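"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from eegclust import (
    MetricTable,
    SynthConfig,
    extract_feature_matrix,
    generate_dataset,
)

# Published six-algorithm comparison table used as *input* to the composite
# scorer: silhouette (SC), Calinski-Harabasz (CH) and Davies-Bouldin (DBI)
# per clustering algorithm; SC/CH bigger-better, DBI smaller-better.
ALGORITHMS = ["GMM", "K-means", "K-medoids", "ISODATA", "DBSCAN", "SSA-DBSCAN"]
INDEX_TABLE = np.array(
    [
        [0.5822, 2242.194, 0.81623],
        [0.6464, 3032.312, 0.75618],
        [0.6277, 3863.054, 0.70741],
        [0.6101, 3432.406, 0.72068],
        [0.6318, 4226.564, 0.61713],
        [0.6775, 4615.198, 0.53475],
    ]
)

# Ten IMF-vs-signal correlation coefficients from a published CEEMDAN
# decomposition of an epileptic EEG segment; input to the screening rule.
IMF_CORRELATIONS = [
    0.1698, 0.1525, 0.3884, 0.5431, 0.6904,
    0.7746, 0.3233, 0.0466, 0.0235, 0.0193,
]


@pytest.fixture(scope="session")
def dataset150():
    """Default three-stage synthetic dataset: 150 segments of 1024 samples."""
    return generate_dataset(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def features150(dataset150):
    return extract_feature_matrix(dataset150.segments)


@pytest.fixture(scope="session")
def blobs3():
    """Three tight, well-separated 2-D Gaussian blobs (50 points each)."""
    rng = np.random.default_rng(0)
    pts = np.vstack(
        [rng.normal(c, 0.3, size=(50, 2)) for c in [(0, 0), (5, 5), (10, 0)]]
    )
    labels = np.repeat([0, 1, 2], 50)
    return pts, labels


@pytest.fixture()
def metric_table():
    return MetricTable(
        object_names=list(ALGORITHMS),
        indicator_names=["SC", "CH", "DBI"],
        values=INDEX_TABLE.copy(),
        polarity=["positive", "positive", "negative"],
    )


def canonical_labels(labels) -> list[int]:
    """Relabel clusters by first appearance so partitions compare equal."""
    mapping: dict[int, int] = {}
    out = []
    for v in labels:
        if v == -1:
            out.append(-1)
            continue
        if v not in mapping:
            mapping[v] = len(mapping)
        out.append(mapping[v])
    return out


def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Brute-force density-reachability closure, independent of the
    implementation under test (plain loops + networkx components)."""
    import networkx as nx

    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    core = (d <= eps).sum(axis=1) >= min_pts  # self-inclusive
    g = nx.Graph()
    g.add_nodes_from(i for i in range(n) if core[i])
    for i in range(n):
        for j in range(i + 1, n):
            if core[i] and core[j] and d[i, j] <= eps:
                g.add_edge(i, j)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    labels = np.full(n, -1)
    for ci, comp in enumerate(comps):
        for i in comp:
            labels[i] = ci
    for i in range(n):
        if core[i]:
            continue
        cand = [j for j in range(n) if core[j] and d[i, j] <= eps]
        if cand:
            labels[i] = labels[min(cand, key=lambda j: d[i, j])]
    return labels
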