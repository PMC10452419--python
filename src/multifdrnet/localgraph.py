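"""Seed-centred local graphs via approximate personalized PageRank.

The subnetwork search is confined to a dense neighbourhood of each seed.
That neighbourhood is found by running the approximate PPR push algorithm
on the multiplex walk: probability mass starts split evenly over the
seed's state nodes (1/|L| each), is pushed from a residual vector into a
score vector until every residual drops below eps * degree, and the push
threshold eps is lowered geometrically until the score vector has at
least K nonzero entries.  The K top-scoring state nodes are kept and the
set is augmented to layer-completeness so every included gene is present
in every layer.

Pushes are performed in deterministic batched sweeps: every state node
whose residual exceeds its threshold is pushed simultaneously through a
sparse row operation.  A batch is just a fixed ordering of individual
pushes, so the per-node approximation guarantee and mass conservation of
the sequential algorithm are unchanged.  All persistent state lives in
dictionaries keyed by state index; no dense vector over the full
state-node space is allocated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .multiplex import MultiplexNetwork, WalkModel

__all__ = ["PPRState", "LocalGraph", "approximate_ppr", "extract_local_graph"]

DEFAULT_TELEPORT = 0.998  # walk-continuation probability c (restart prob 1 - c)
EPS_FLOOR = 1e-10


@dataclass
class PPRState:
    """Sparse scores/residual pair of the push algorithm; resumable."""

    scores: dict[int, float]
    residual: dict[int, float]
    epsilon: float
    teleport: float

    @property
    def total_mass(self) -> float:
        return sum(self.scores.values()) + sum(self.residual.values())


@dataclass
class LocalGraph:
    """Layer-complete set of state nodes around one seed gene."""

    seed: str
    state_nodes: frozenset[int]
    physical_nodes: frozenset[str]
    K: int
    boundary_weights: dict[str, float] = field(default_factory=dict)
    scores: dict[int, float] = field(default_factory=dict)


def approximate_ppr(
    walk: WalkModel,
    M: MultiplexNetwork,
    seed: str,
    teleport: float = DEFAULT_TELEPORT,
    epsilon: float = 1e-5,
    state: PPRState | None = None,
) -> PPRState:
    """Push-style approximate PPR from all state nodes of ``seed``.

    While some state node u has residual(u) > epsilon * deg(u), the push
    moves (1 - c) of residual(u) into scores(u) and spreads c * residual(u)
    along the walk's transition row into neighbouring residuals (c is the
    continuation probability ``teleport``).  All currently eligible nodes
    are pushed per sweep, in ascending state-index order, so the result is
    deterministic.  Passing a previous ``state`` resumes the computation
    at a smaller epsilon (residuals stay valid across epsilon decreases).
    """
    if not 0 < teleport < 1:
        raise ValueError("teleport must be in (0, 1)")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if seed not in M.gene_index:
        raise KeyError(f"seed gene {seed!r} is not in the multiplex network")
    if seed in walk.unwalkable_genes:
        raise KeyError(f"seed gene {seed!r} is isolated and unwalkable")

    c = teleport
    L = M.n_layers
    if state is None:
        residual = {M.state_index(seed, a): 1.0 / L for a in range(L)}
        scores: dict[int, float] = {}
    else:
        residual = dict(state.residual)
        scores = dict(state.scores)

    T = walk.transition
    deg = walk.degrees
    while True:
        eligible = sorted(
            u for u, r in residual.items() if deg[u] > 0 and r > epsilon * deg[u]
        )
        if not eligible:
            break
        U = np.asarray(eligible, dtype=np.int64)
        rU = np.asarray([residual[u] for u in eligible])
        for u, r in zip(eligible, rU):
            scores[u] = scores.get(u, 0.0) + (1.0 - c) * r
            residual[u] = 0.0
        rows = T[U]
        spread = rows.data * np.repeat(c * rU, np.diff(rows.indptr))
        cols, inv = np.unique(rows.indices, return_inverse=True)
        added = np.bincount(inv, weights=spread)
        for v, a in zip(cols.tolist(), added.tolist()):
            residual[v] = residual.get(v, 0.0) + a
    residual = {u: r for u, r in residual.items() if r > 0}
    return PPRState(scores=scores, residual=residual, epsilon=epsilon, teleport=c)


def extract_local_graph(
    walk: WalkModel,
    M: MultiplexNetwork,
    seed: str,
    K: int = 400,
    teleport: float = DEFAULT_TELEPORT,
) -> LocalGraph:
    """Extract the layer-complete local graph of up to K state nodes.

    Runs :func:`approximate_ppr` with a geometric epsilon schedule
    (start 1/(50 K), divide by 10, floor 1e-10) until the score vector has
    at least K nonzero entries or the floor is reached, keeps the K
    top-scoring state nodes (ties by gene identifier then layer index),
    then augments to layer-completeness and records per-gene boundary
    weights (total intralayer edge weight leaving the local graph).
    """
    if K < M.n_layers:
        raise ValueError("K must be at least the number of layers")
    eps = 1.0 / (50.0 * K)
    state = approximate_ppr(walk, M, seed, teleport=teleport, epsilon=eps)
    while len(state.scores) < K and eps > EPS_FLOOR:
        eps /= 10.0
        state = approximate_ppr(
            walk, M, seed, teleport=teleport, epsilon=eps, state=state
        )
    if len(state.scores) < K:
        warnings.warn(
            f"component around seed {seed!r} has only {len(state.scores)} "
            f"reachable state nodes (< K = {K}); using the whole reachable set",
            stacklevel=2,
        )
    # rank: score desc, then gene identifier, then layer index
    def sort_key(item):
        u, s = item
        gene, layer = M.state_to_gene_layer(u)
        return (-s, gene, layer)

    ranked = sorted(state.scores.items(), key=sort_key)
    top = {u for u, _ in ranked[:K]}
    # always keep the seed's own state nodes
    top.update(M.state_index(seed, a) for a in range(M.n_layers))
    # augment to layer-completeness
    genes = {M.state_to_gene_layer(u)[0] for u in top}
    states = frozenset(
        M.state_index(g, a) for g in genes for a in range(M.n_layers)
    )
    # per-gene boundary weight: intralayer edge weight to genes outside
    boundary: dict[str, float] = {g: 0.0 for g in genes}
    for layer in M.layers:
        for e in layer.edges:
            a, b = tuple(e)
            a_in, b_in = a in genes, b in genes
            if a_in and not b_in:
                boundary[a] += layer.weight
            elif b_in and not a_in:
                boundary[b] += layer.weight
    return LocalGraph(
        seed=seed,
        state_nodes=states,
        physical_nodes=frozenset(genes),
        K=K,
        boundary_weights=boundary,
        scores=dict(state.scores),
    )
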