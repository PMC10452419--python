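"""Planted-module simulation benchmark and evaluation metrics.

The generator emulates the standard signal-to-noise benchmark for
perturbed-subnetwork detection: a scaffold graph carries a handful of
planted dense modules (the "target subnetworks") over a sparse random
background; each multiplex layer is an independent degree-preserving
rewiring of the scaffold; p-values are drawn Beta(a, 1) for module genes
(small a = strong signal) and U(0, 1) for background genes.  Evaluation
uses the gene-level F score, the symmetric size-weighted best-match
Fsub score between subnetwork collections, and the exact per-subnetwork
FDR (proportion of non-target genes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .multiplex import LayerNetwork
from .scores import GeneScoreTable
from .search import Subnetwork

__all__ = [
    "BenchmarkScenario",
    "EvaluationReport",
    "generate_scenario",
    "rewire_degree_preserving",
    "f_score",
    "fsub_symmetric",
    "evaluate",
]


@dataclass
class BenchmarkScenario:
    """Configuration of one synthetic planted-module experiment."""

    n_genes: int = 500
    n_layers: int = 3
    n_modules: int = 5
    module_size_range: tuple[int, int] = (10, 50)
    a: float = 0.01  # Beta(a, 1) signal parameter; smaller = stronger
    rewire_fraction: float = 0.1
    background_degree: float = 4.0
    module_density: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("beta parameter a must be positive")
        lo, hi = self.module_size_range
        if self.n_modules * hi > self.n_genes:
            raise ValueError("planted modules cannot exceed the gene universe")


@dataclass
class EvaluationReport:
    """Gene-level F, module-level Fsub, and per-subnetwork FDRs."""

    f_score: float
    fsub: float
    exact_fdr: list[float] = field(default_factory=list)
    est_fdr: list[float] = field(default_factory=list)
    n_detected: int = 0


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def rewire_degree_preserving(
    layer: LayerNetwork, n_swaps: int, rng_seed: int
) -> LayerNetwork:
    """Randomize a layer by repeated double-edge swaps.

    Each attempted swap picks two distinct edges (a, b), (c, d) and
    replaces them with (a, d), (c, b); swaps creating self-loops or
    multi-edges are rejected, so the degree sequence is preserved exactly.
    """
    if layer.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(rng_seed)
    edges = [tuple(sorted(e)) for e in layer.edges]
    edges.sort()
    edge_set = set(edges)
    n_edges = len(edges)
    for _ in range(n_swaps):
        k1, k2 = rng.integers(0, n_edges, size=2)
        if k1 == k2:
            continue
        a, b = edges[k1]
        c, d = edges[k2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[k1])
        edge_set.discard(edges[k2])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[k1], edges[k2] = e1, e2
    return LayerNetwork(
        name=layer.name,
        edges={frozenset(e) for e in edge_set},
        genes=set(layer.genes),
        weight=layer.weight,
    )


def generate_scenario(
    scenario: BenchmarkScenario,
) -> tuple[list[LayerNetwork], list[set[str]], dict[str, float]]:
    """Generate multiplex layers, planted modules and synthetic p-values.

    Returns ``(layers, truth, pvalues)`` where ``truth`` is the list of
    planted gene sets.  Fully deterministic given ``scenario.rng_seed``.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    genes = _gene_names(scenario.n_genes)

    # disjoint planted modules
    lo, hi = scenario.module_size_range
    sizes = rng.integers(lo, hi + 1, size=scenario.n_modules)
    pool = rng.permutation(scenario.n_genes)
    truth: list[set[str]] = []
    start = 0
    for sz in sizes:
        truth.append({genes[i] for i in pool[start : start + sz]})
        start += sz

    # scaffold: sparse Erdos-Renyi background + dense module blocks
    n = scenario.n_genes
    p_bg = scenario.background_degree / (n - 1)
    edges: set[tuple[str, str]] = set()
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p_bg
    for i, j in zip(iu[keep], ju[keep]):
        edges.add((genes[i], genes[j]))
    for module in truth:
        members = sorted(module)
        for a, b in itertools.combinations(members, 2):
            if rng.random() < scenario.module_density:
                edges.add(tuple(sorted((a, b))))

    scaffold = LayerNetwork(
        name="scaffold",
        edges={frozenset(e) for e in edges},
        genes=set(genes),
        weight=1.0,
    )

    # layers: independent degree-preserving rewirings of the scaffold
    # (each successful double-edge swap rewires two edges)
    layers: list[LayerNetwork] = []
    n_swaps = int(round(scenario.rewire_fraction * scaffold.n_edges / 2))
    for li in range(scenario.n_layers):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if scenario.rewire_fraction > 0 and scaffold.n_edges >= 2:
            ly = rewire_degree_preserving(scaffold, n_swaps, rng_seed=sub_seed)
        else:
            ly = LayerNetwork(
                name="scaffold",
                edges=set(scaffold.edges),
                genes=set(genes),
                weight=1.0,
            )
        ly.name = f"layer{li}"
        layers.append(ly)

    # p-values: Beta(a, 1) on module genes, U(0, 1) on background
    target = set().union(*truth) if truth else set()
    pvalues: dict[str, float] = {}
    for g in genes:
        if g in target:
            pvalues[g] = float(rng.beta(scenario.a, 1.0))
        else:
            pvalues[g] = float(rng.uniform())
    return layers, truth, pvalues


def f_score(target_genes: set[str], detected_genes: set[str]) -> float:
    """Harmonic mean of gene-level precision and recall; 0 if none detected."""
    if not target_genes:
        raise ValueError("target gene set is empty")
    if not detected_genes:
        return 0.0
    tp = len(target_genes & detected_genes)
    if tp == 0:
        return 0.0
    precision = tp / len(detected_genes)
    recall = tp / len(target_genes)
    return 2 * precision * recall / (precision + recall)


def fsub_symmetric(A: list[set[str]], B: list[set[str]]) -> float:
    """Symmetric size-weighted best-match F between two subnetwork lists.

    Each subnetwork in A is matched with its best-F counterpart in B and
    vice versa; matches are weighted by subnetwork size and the two
    directions averaged.
    """
    if not A or not B:
        raise ValueError("both subnetwork lists must be nonempty")
    if any(not s for s in A) or any(not s for s in B):
        raise ValueError("subnetworks must be nonempty")

    def directed(X: list[set[str]], Y: list[set[str]]) -> float:
        total = sum(len(x) for x in X)
        return (
            sum(len(x) * max(f_score(x, y) for y in Y) for x in X) / total
        )

    return 0.5 * (directed(A, B) + directed(B, A))


def evaluate(
    detected: list[Subnetwork],
    truth: list[set[str]],
    table: GeneScoreTable | None = None,
) -> EvaluationReport:
    """Score detected subnetworks against the planted ground truth."""
    if not truth:
        raise ValueError("ground truth is empty")
    target_genes = set().union(*truth)
    detected_sets = [set(s.genes) for s in detected]
    detected_genes = set().union(*detected_sets) if detected_sets else set()
    f = f_score(target_genes, detected_genes)
    fsub = fsub_symmetric(truth, detected_sets) if detected_sets else 0.0
    exact = [
        len(s - target_genes) / len(s) for s in detected_sets
    ]
    est = [s.est_fdr for s in detected]
    return EvaluationReport(
        f_score=f,
        fsub=fsub,
        exact_fdr=exact,
        est_fdr=est,
        n_detected=len(detected),
    )
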