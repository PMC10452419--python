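"""Multiplex network construction and the classic random walk on it.

A collection of protein-protein interaction networks is modelled as a
multiplex network: every gene (physical node) is represented by one state
node per layer, intralayer edges are copied verbatim from the input
networks, and every pair of state nodes that represents the same gene in
two different layers is joined by an interlayer edge.  The classic random
walk on this (weighted, undirected) structure supplies the transition
matrix, the stationary distribution and the generalized conductance score
used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LayerNetwork",
    "MultiplexNetwork",
    "WalkModel",
    "build_multiplex",
    "walk_model",
    "conductance",
    "aggregate_network",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Invalid user configuration (bad layer list, weights, ...)."""


def _normalize_gene(g: str) -> str:
    return str(g).strip()


@dataclass
class LayerNetwork:
    """One undirected, unweighted-per-edge network layer.

    ``weight`` applies uniformly to every edge of the layer; it is the
    per-layer emphasis weight w (default 1, set >1 to emphasise a layer).
    """

    name: str
    edges: set[frozenset[str]] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigurationError(f"layer {self.name!r}: weight must be positive")
        cleaned: set[frozenset[str]] = set()
        genes = {_normalize_gene(g) for g in self.genes}
        for e in self.edges:
            pair = [_normalize_gene(g) for g in e]
            if len(set(pair)) < 2:
                continue  # self-loop
            cleaned.add(frozenset(pair))
            genes.update(pair)
        self.edges = cleaned
        self.genes = genes

    @classmethod
    def from_edge_list(
        cls,
        name: str,
        edge_list: Iterable[tuple[str, str]],
        weight: float = 1.0,
        isolated_genes: Iterable[str] = (),
    ) -> "LayerNetwork":
        edges = {frozenset((a, b)) for a, b in edge_list}
        return cls(name=name, edges=edges, genes=set(isolated_genes), weight=weight)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class MultiplexNetwork:
    """Multiplex network over physical genes ``genes`` and ``layers``.

    State nodes are indexed implicitly as ``layer_index * n_genes +
    gene_index``; they are never materialised as objects.
    """

    genes: tuple[str, ...]
    layers: list[LayerNetwork]
    interlayer_weight: float = 1.0
    gene_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.gene_index:
            self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_states(self) -> int:
        return self.n_genes * self.n_layers

    def state_index(self, gene: str, layer: int) -> int:
        return layer * self.n_genes + self.gene_index[gene]

    def state_to_gene_layer(self, state: int) -> tuple[str, int]:
        layer, gi = divmod(state, self.n_genes)
        return self.genes[gi], layer

    def states_of(self, genes: Iterable[str]) -> list[int]:
        """All state nodes of the given genes (a cover-respecting set)."""
        out = []
        for g in genes:
            gi = self.gene_index[g]
            out.extend(layer * self.n_genes + gi for layer in range(self.n_layers))
        return out


def build_multiplex(
    layers: Sequence[LayerNetwork], interlayer_weight: float = 1.0
) -> MultiplexNetwork:
    """Assemble a multiplex network from per-layer edge lists.

    The physical node set is the union of all layer gene sets; a state node
    exists for every (gene, layer) pair even when the gene is absent from
    that layer's input.
    """
    if not layers:
        raise ConfigurationError("at least one layer is required")
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate layer names: {names}")
    for ly in layers:
        if not ly.genes:
            raise ConfigurationError(f"layer {ly.name!r} is empty")
    if interlayer_weight <= 0:
        raise ConfigurationError("interlayer_weight must be positive")
    genes = tuple(sorted(set().union(*(ly.genes for ly in layers))))
    return MultiplexNetwork(
        genes=genes, layers=list(layers), interlayer_weight=interlayer_weight
    )


@dataclass
class WalkModel:
    """Classic random walk over the state nodes of a multiplex network.

    ``adjacency`` is the symmetric weighted adjacency A including the
    interlayer edges; ``transition`` is the row-stochastic T = D^-1 A;
    ``stationary`` is the degree-proportional stationary distribution p.
    Genes flagged ``unwalkable`` (isolated genes in a single-layer
    multiplex) have an all-zero row and are excluded from local graphs.
    """

    adjacency: sp.csr_matrix
    transition: sp.csr_matrix
    degrees: np.ndarray
    stationary: np.ndarray
    unwalkable_genes: frozenset[str]

    def tadj_row(self, state: int) -> np.ndarray:
        """State-node neighbours under the binary adjacency T_adj."""
        row = self.transition.getrow(state)
        return row.indices[row.data > 0]


def _multiplex_adjacency(M: MultiplexNetwork) -> sp.csr_matrix:
    n, L = M.n_genes, M.n_layers
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for li, layer in enumerate(M.layers):
        off = li * n
        for e in layer.edges:
            a, b = tuple(e)
            ia, ib = M.gene_index[a], M.gene_index[b]
            rows += [off + ia, off + ib]
            cols += [off + ib, off + ia]
            vals += [layer.weight, layer.weight]
    if L > 1:
        w = M.interlayer_weight
        for gi in range(n):
            for a in range(L):
                for b in range(a + 1, L):
                    rows += [a * n + gi, b * n + gi]
                    cols += [b * n + gi, a * n + gi]
                    vals += [w, w]
    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(M.n_states, M.n_states), dtype=float
    )
    A.sum_duplicates()
    return A


def walk_model(M: MultiplexNetwork) -> WalkModel:
    """Build the classic-walk transition structure of a multiplex network.

    The stationary distribution of the classic walk on an undirected
    weighted graph is degree-proportional, so it is computed in closed form
    as p(i) = deg(i) / sum(deg).
    """
    A = _multiplex_adjacency(M)
    deg = np.asarray(A.sum(axis=1)).ravel()
    unwalkable: set[str] = set()
    if M.n_layers == 1:
        for gi in np.nonzero(deg == 0)[0]:
            unwalkable.add(M.genes[int(gi)])
        if unwalkable:
            warnings.warn(
                f"{len(unwalkable)} isolated gene(s) in a single-layer multiplex "
                "are unwalkable and excluded from local graphs",
                stacklevel=2,
            )
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    T = sp.diags(inv) @ A
    p = deg / deg.sum()
    return WalkModel(
        adjacency=A,
        transition=T.tocsr(),
        degrees=deg,
        stationary=p,
        unwalkable_genes=frozenset(unwalkable),
    )


def _as_state_indices(M: MultiplexNetwork, S: Iterable) -> np.ndarray:
    idx = []
    for s in S:
        if isinstance(s, (int, np.integer)):
            idx.append(int(s))
        else:
            gene, layer = s
            idx.append(M.state_index(gene, int(layer)))
    return np.asarray(sorted(set(idx)), dtype=int)


def conductance(M: MultiplexNetwork, walk: WalkModel, S: Iterable) -> float:
    """Generalized conductance of a state-node set S.

    Equals the stationary outflow of the classic walk from S divided by the
    stationary mass in S, which for an undirected weighted graph reduces to
    cut-weight(S) / volume(S).  ``S`` may hold raw state indices or
    ``(gene, layer)`` pairs.
    """
    idx = _as_state_indices(M, S)
    if idx.size == 0:
        raise ValueError("S must be nonempty")
    if idx.size >= M.n_states:
        raise ValueError("S must be a proper subset of the state nodes")
    mask = np.zeros(M.n_states, dtype=bool)
    mask[idx] = True
    sub = walk.adjacency[idx]  # rows of S
    outside = ~mask[sub.indices]
    cut = float(sub.data[outside].sum())
    volume = float(walk.degrees[idx].sum())
    if volume == 0:
        return 0.0
    return cut / volume


def aggregate_network(M: MultiplexNetwork) -> LayerNetwork:
    """Union of all layer edge sets as one unweighted network on V."""
    edges: set[frozenset[str]] = set()
    for ly in M.layers:
        edges |= ly.edges
    return LayerNetwork(name="aggregate", edges=edges, genes=set(M.genes), weight=1.0)
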