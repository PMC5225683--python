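"""Shared fixtures: reduced phantom volumes and full pipeline runs.

The end-to-end fixtures use the 40x256x256 reduced presets so the whole
suite stays within a desktop-scale budget; geometry is fractional, so the
same specs render at 512x512 via the ``shape`` argument.
"""

from __future__ import annotations

import numpy as np
import pytest

from liverwalker.metrics import compute_report
from liverwalker.phantom import generate_phantom, make_test_suite
from liverwalker.pipeline import liver_mask, segment_series

REDUCED_SHAPE = (40, 256, 256)


@pytest.fixture(scope="session")
def healthy_phantom():
    spec = make_test_suite("healthy", shape=REDUCED_SHAPE)
    volume, masks, spec = generate_phantom(spec)
    return spec, volume, masks


@pytest.fixture(scope="session")
def multi_lesion_phantom():
    spec = make_test_suite("multi-lesion", shape=REDUCED_SHAPE)
    volume, masks, spec = generate_phantom(spec)
    return spec, volume, masks


@pytest.fixture(scope="session")
def healthy_run(healthy_phantom):
    """Full pipeline on the healthy preset (labels, diagnostics, report)."""
    spec, volume, masks = healthy_phantom
    labels, diag, _ = segment_series(volume)
    report = compute_report(liver_mask(labels), masks["liver"])
    return labels, diag, report


@pytest.fixture(scope="session")
def multi_lesion_run(multi_lesion_phantom):
    spec, volume, masks = multi_lesion_phantom
    labels, diag, _ = segment_series(volume)
    report = compute_report(liver_mask(labels), masks["liver"])
    return labels, diag, report


def dense_constrained_solve(graph) -> np.ndarray:
    """Independent oracle for the Dirichlet solve.

    Builds the full dense combinatorial Laplacian edge by edge, replaces
    each seeded row with an identity row carrying the one-hot boundary
    value, and solves the complete n x n system per label — no block
    decomposition, no sparse path, no complement shortcut.
    """
    n = graph.n_nodes
    lap = np.zeros((n, n))
    for (i, j), w in zip(graph.edges, graph.weights):
        lap[i, j] -= w
        lap[j, i] -= w
        lap[i, i] += w
        lap[j, j] += w
    out = np.zeros((len(graph.labels), n))
    for k, lab in enumerate(graph.labels):
        a = lap.copy()
        b = np.zeros(n)
        for s in graph.seeded:
            a[s, :] = 0.0
            a[s, s] = 1.0
            b[s] = 1.0 if graph.seed_labels[s] == lab else 0.0
        out[k] = np.linalg.solve(a, b)
    return out


def random_grid_graph(rng: np.random.Generator):
    """Random small weighted pixel graph with random seeds and labels."""
    from liverwalker.random_walker import WeightedPixelGraph, _grid_edges

    h, w = rng.integers(2, 13, 2)
    conn = int(rng.choice([4, 8]))
    edges = _grid_edges((int(h), int(w)), conn)
    weights = rng.uniform(0.01, 2.0, len(edges))
    seed_labels = np.zeros(h * w, dtype=np.int64)
    n_lab = int(rng.integers(2, 5))
    for lab in range(1, n_lab + 1):
        seed_labels[rng.integers(0, h * w)] = lab
    labels = tuple(int(l) for l in np.unique(seed_labels) if l != 0)
    return WeightedPixelGraph(
        shape=(int(h), int(w)), edges=edges, weights=weights, seed_labels=seed_labels, labels=labels
    )
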