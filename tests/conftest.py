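"""Shared fixtures: toy multiplexes and random-instance factories."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from multifdrnet import (
    GeneScoreTable,
    LayerNetwork,
    build_multiplex,
    walk_model,
)


@pytest.fixture
def toy_two_layer():
    """Genes {A, B}; layer1 has edge A-B, layer2 has no edges.

    With unit weights: deg(A1) = deg(B1) = 2, deg(A2) = deg(B2) = 1,
    so p = (1/3, 1/3, 1/6, 1/6).
    """
    l1 = LayerNetwork.from_edge_list("L1", [("A", "B")])
    l2 = LayerNetwork.from_edge_list("L2", [], isolated_genes=["A", "B"])
    M = build_multiplex([l1, l2], interlayer_weight=1.0)
    return M, walk_model(M)


@pytest.fixture
def clique_path_multiplex():
    """6-gene clique joined by a single edge to a 6-gene path, two layers.

    Clique genes carry lfdr 0.01, path genes 0.9 — the planted search
    instance whose optimum is exactly the clique at B = 0.1.
    """
    clique = [f"C{i}" for i in range(6)]
    path = [f"P{i}" for i in range(6)]
    edges = (
        list(itertools.combinations(clique, 2))
        + [(path[i], path[i + 1]) for i in range(5)]
        + [("C0", "P0")]
    )
    l1 = LayerNetwork.from_edge_list("L1", edges)
    l2 = LayerNetwork.from_edge_list("L2", edges)
    M = build_multiplex([l1, l2])
    lfdr = {g: 0.01 for g in clique} | {g: 0.9 for g in path}
    return M, walk_model(M), GeneScoreTable.from_lfdr(lfdr), set(clique)


def random_multiplex(rng: np.random.Generator, n_genes=None, n_layers=None,
                     edge_prob=0.25, weights=None):
    """Random multi-layer multiplex for property tests (<= 200 state nodes)."""
    if n_genes is None:
        n_genes = int(rng.integers(5, 30))
    if n_layers is None:
        n_layers = int(rng.integers(1, 4))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    layers = []
    for a in range(n_layers):
        edges = {
            (genes[i], genes[j])
            for i in range(n_genes)
            for j in range(i + 1, n_genes)
            if rng.random() < edge_prob
        }
        if not edges:  # keep the layer nonempty
            edges = {(genes[0], genes[1])}
        w = 1.0 if weights is None else weights[a]
        layers.append(
            LayerNetwork.from_edge_list(f"L{a}", edges, weight=w, isolated_genes=genes)
        )
    return build_multiplex(layers)


def power_iteration_stationary(T, n_steps=10_000):
    """Independent oracle for the stationary distribution: iterate p <- T'p."""
    n = T.shape[0]
    p = np.full(n, 1.0 / n)
    Tt = T.T.tocsr()
    for _ in range(n_steps):
        p_next = Tt @ p
        s = p_next.sum()
        p_next /= s
        if np.abs(p_next - p).max() < 1e-15:
            return p_next
        p = p_next
    return p


def conductance_eq1(M, walk, state_nodes):
    """Independent term-by-term evaluation of the conductance definition:
    sum_{i in S, j not in S} T[i, j] p[i] / sum_{i in S} p[i]."""
    idx = set()
    for s in state_nodes:
        idx.add(s if isinstance(s, (int, np.integer)) else M.state_index(s[0], s[1]))
    T = walk.transition
    p = walk.stationary
    num = 0.0
    for i in idx:
        row = T.getrow(i)
        for j, t in zip(row.indices, row.data):
            if int(j) not in idx:
                num += t * p[i]
    den = sum(p[i] for i in idx)
    return num / den
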