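"""Minimum-conductance, FDR-bounded subnetwork search.

For each seed the search solves: minimize the generalized conductance
Phi(S) of a cover-respecting subnetwork S = P x L inside the seed's local
graph, subject to (i) mean local FDR of P at most B, (ii) the seed in P,
and (iii) P connected in the physical local-graph adjacency (the union
over layers of intralayer edges; under the cover constraint this is
equivalent to random-walk connectivity of S, because interlayer edges
link each gene's state nodes).

Because the cover constraint collapses each gene's state-node variables
into one binary x_i, the cut and volume of S are linear in x:

    N(x) = sum_{i<j} c_ij |x_i - x_j| + sum_i b_i x_i   (cut weight)
    D(x) = sum_i d_i x_i                                (volume)

with c_ij the total layer weight of edges (i, j) inside the local graph,
b_i the boundary weight to genes outside it, and d_i the gene's total
state-node degree in the full multiplex (interlayer edges included).
The ratio N/D is minimized by Dinkelbach iteration: each subproblem
min N(x) - lambda * D(x) is a MILP (|x_i - x_j| linearized, connectivity
enforced by single-commodity flow) solved with HiGHS via scipy.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .localgraph import LocalGraph, extract_local_graph
from .multiplex import MultiplexNetwork, WalkModel
from .scores import GeneScoreTable, SeedList

__all__ = ["SearchInstance", "Subnetwork", "build_instance", "solve_subnetwork", "detect_all"]

logger = logging.getLogger(__name__)

DINKELBACH_TOL = 1e-7
MAX_DINKELBACH_ITER = 50
MIP_GAP = 1e-6


@dataclass
class SearchInstance:
    """Linearized cut/volume data for one seed's local graph."""

    genes: list[str]  # sorted physical genes of the local graph
    seed: str
    B: float
    cut_coeffs: dict[tuple[int, int], float]  # (i, j) with i < j -> c_ij
    boundary: np.ndarray  # b_i
    volume: np.ndarray  # d_i
    lfdr: np.ndarray  # w_i
    local: LocalGraph | None = None

    @property
    def n(self) -> int:
        return len(self.genes)

    def cut_volume(self, members: np.ndarray) -> tuple[float, float]:
        """Cut weight N and volume D of the gene subset given as a 0/1 vector."""
        x = np.asarray(members, dtype=float)
        N = float(self.boundary @ x)
        for (i, j), c in self.cut_coeffs.items():
            N += c * abs(x[i] - x[j])
        return N, float(self.volume @ x)


@dataclass
class Subnetwork:
    """One detected subnetwork: gene set, conductance and estimated FDR."""

    seed: str
    genes: frozenset[str]
    conductance: float
    est_fdr: float
    status: str  # optimal | incumbent | singleton-fallback
    dinkelbach_iterations: int = 0
    log: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genes": sorted(self.genes),
            "conductance": self.conductance,
            "est_fdr": self.est_fdr,
            "status": self.status,
        }


def build_instance(
    local: LocalGraph,
    M: MultiplexNetwork,
    walk: WalkModel,
    table: GeneScoreTable,
    B: float,
) -> SearchInstance:
    """Assemble the cut/volume coefficients of Eq.-style conductance.

    For any seed-containing gene set P, N(P) equals the total cut weight of
    S = P x L in the full multiplex and D(P) its volume, so N/D equals the
    generalized conductance exactly.
    """
    genes = sorted(local.physical_nodes)
    gidx = {g: i for i, g in enumerate(genes)}
    cut: dict[tuple[int, int], float] = {}
    for layer in M.layers:
        for e in layer.edges:
            a, b = tuple(e)
            if a in gidx and b in gidx:
                i, j = sorted((gidx[a], gidx[b]))
                cut[(i, j)] = cut.get((i, j), 0.0) + layer.weight
    boundary = np.array([local.boundary_weights.get(g, 0.0) for g in genes])
    n_genes = M.n_genes
    vol = np.array(
        [
            sum(
                walk.degrees[a * n_genes + M.gene_index[g]]
                for a in range(M.n_layers)
            )
            for g in genes
        ]
    )
    unscored = sum(not table.has(g) for g in genes)
    if unscored:
        warnings.warn(
            f"{unscored} local-graph gene(s) without scores treated as lfdr = 1",
            stacklevel=2,
        )
    lfdr = np.array([table.lfdr(g) for g in genes])
    return SearchInstance(
        genes=genes,
        seed=local.seed,
        B=B,
        cut_coeffs=cut,
        boundary=boundary,
        volume=vol,
        lfdr=lfdr,
        local=local,
    )


def _build_milp_matrices(inst: SearchInstance):
    """Constraint matrix shared by all Dinkelbach subproblems.

    Variables: x (n binary), y_e (one per internal edge, in [0, 1]),
    flow f (two arcs per internal edge, in [0, n-1]).
    """
    n = inst.n
    edges = sorted(inst.cut_coeffs)
    m = len(edges)
    s = inst.genes.index(inst.seed)
    nvar = n + m + 2 * m
    big = max(n - 1, 1)

    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0

    def add(coefs: dict[int, float], lo: float, hi: float):
        nonlocal r
        for cvar, cval in coefs.items():
            rows.append(r)
            cols.append(cvar)
            vals.append(cval)
        lb.append(lo)
        ub.append(hi)
        r += 1

    # FDR constraint: sum (w_i - B) x_i <= 0
    add({i: inst.lfdr[i] - inst.B for i in range(n)}, -np.inf, 0.0)

    # |x_i - x_j| linearization for each internal edge
    for k, (i, j) in enumerate(edges):
        yv = n + k
        add({i: 1.0, j: -1.0, yv: -1.0}, -np.inf, 0.0)
        add({i: -1.0, j: 1.0, yv: -1.0}, -np.inf, 0.0)
        add({i: -1.0, j: -1.0, yv: 1.0}, -np.inf, 0.0)
        add({i: 1.0, j: 1.0, yv: 1.0}, -np.inf, 2.0)

    # single-commodity flow connectivity on the physical adjacency
    arc_of = {}
    for k, (i, j) in enumerate(edges):
        arc_of[(i, j)] = n + m + 2 * k
        arc_of[(j, i)] = n + m + 2 * k + 1
    for (u, v), fvar in arc_of.items():
        add({fvar: 1.0, u: -big}, -np.inf, 0.0)  # f_uv <= (n-1) x_u
        add({fvar: 1.0, v: -big}, -np.inf, 0.0)  # f_uv <= (n-1) x_v
    # conservation: inflow - outflow = x_u for u != seed;
    # seed: outflow - inflow = sum_{u != seed} x_u
    for u in range(n):
        coefs: dict[int, float] = {}
        for (a, b), fvar in arc_of.items():
            if b == u:
                coefs[fvar] = coefs.get(fvar, 0.0) + (1.0 if u != s else -1.0)
            elif a == u:
                coefs[fvar] = coefs.get(fvar, 0.0) - (1.0 if u != s else -1.0)
        if u != s:
            coefs[u] = coefs.get(u, 0.0) - 1.0
            add(coefs, 0.0, 0.0)
        else:
            for w in range(n):
                if w != s:
                    coefs[w] = coefs.get(w, 0.0) - 1.0
            add(coefs, 0.0, 0.0)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    constraint = LinearConstraint(A, np.array(lb), np.array(ub))

    vlb = np.zeros(nvar)
    vub = np.concatenate([np.ones(n + m), np.full(2 * m, float(big))])
    vlb[s] = 1.0  # seed constraint
    integrality = np.concatenate([np.ones(n), np.zeros(m + 2 * m)])
    return edges, constraint, Bounds(vlb, vub), integrality


def solve_subnetwork(
    inst: SearchInstance, time_limit: float = 600.0
) -> Subnetwork:
    """Solve the fractional program by Dinkelbach iteration over MILPs.

    Each subproblem minimizes N(x) - lambda * D(x); lambda is updated to
    the incumbent ratio until the improvement drops below 1e-7.  On solver
    timeout the best feasible incumbent is returned (status ``incumbent``);
    with no incumbent at all, the singleton {seed} is returned when its
    lfdr satisfies the bound (status ``singleton-fallback``).
    """
    s = inst.genes.index(inst.seed)
    if inst.lfdr[s] > inst.B:
        raise ValueError(
            f"seed {inst.seed!r} has lfdr {inst.lfdr[s]:.4g} > B = {inst.B}: infeasible"
        )
    n = inst.n
    edges, constraint, bounds, integrality = _build_milp_matrices(inst)
    m = len(edges)

    def singleton() -> Subnetwork:
        x0 = np.zeros(n)
        x0[s] = 1.0
        N, D = inst.cut_volume(x0)
        return Subnetwork(
            seed=inst.seed,
            genes=frozenset([inst.seed]),
            conductance=N / D if D > 0 else 0.0,
            est_fdr=float(inst.lfdr[s]),
            status="singleton-fallback",
        )

    # initial lambda: conductance of the singleton {seed}
    x = np.zeros(n)
    x[s] = 1.0
    N, D = inst.cut_volume(x)
    lam = N / D if D > 0 else 0.0
    best_x, best_lam = x, lam
    deadline = time.monotonic() + time_limit
    timed_out = False
    iters = 0
    for iters in range(1, MAX_DINKELBACH_ITER + 1):
        remaining = deadline - time.monotonic()
        if remaining <= 0:
            timed_out = True
            break
        c_obj = np.zeros(n + 3 * m)
        c_obj[:n] = inst.boundary - lam * inst.volume
        for k, e in enumerate(edges):
            c_obj[n + k] = inst.cut_coeffs[e]
        res = milp(
            c=c_obj,
            constraints=constraint,
            integrality=integrality,
            bounds=bounds,
            options={"mip_rel_gap": MIP_GAP, "time_limit": remaining},
        )
        if res.x is None:
            timed_out = res.status == 1
            break
        xk = np.round(res.x[:n])
        Nk, Dk = inst.cut_volume(xk)
        Fk = Nk - lam * Dk
        if res.status == 1:  # hit the time limit with an incumbent
            timed_out = True
            if Dk > 0 and Nk / Dk < best_lam:
                best_x, best_lam = xk, Nk / Dk
            break
        best_x, best_lam = xk, (Nk / Dk if Dk > 0 else 0.0)
        if Fk >= -DINKELBACH_TOL:
            break
        lam = best_lam

    members = frozenset(inst.genes[i] for i in np.nonzero(best_x > 0.5)[0])
    if not members:
        return singleton()
    est_fdr = float(np.mean([inst.lfdr[inst.genes.index(g)] for g in members]))
    status = "incumbent" if timed_out else "optimal"
    return Subnetwork(
        seed=inst.seed,
        genes=members,
        conductance=float(best_lam),
        est_fdr=est_fdr,
        status=status,
        dinkelbach_iterations=iters,
    )


def detect_all(
    M: MultiplexNetwork,
    walk: WalkModel,
    table: GeneScoreTable,
    seeds: SeedList,
    B: float = 0.1,
    K: int = 400,
    teleport: float = 0.998,
    time_limit: float = 600.0,
) -> list[Subnetwork]:
    """Per-seed detection loop with redundancy skipping.

    Seeds are processed in order; a seed already contained in an earlier
    subnetwork's gene set is skipped.
    """
    results: list[Subnetwork] = []
    covered: set[str] = set()
    for seed in seeds:
        if seed in covered:
            logger.info("seed %s already covered; skipped", seed)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            local = extract_local_graph(walk, M, seed, K=K, teleport=teleport)
        inst = build_instance(local, M, walk, table, B)
        sub = solve_subnetwork(inst, time_limit=time_limit)
        sub.log = {
            "local_graph_genes": len(local.physical_nodes),
            "local_graph_states": len(local.state_nodes),
        }
        logger.info(
            "seed %s: local graph %d genes, %d-gene subnetwork, phi=%.4g, "
            "est_fdr=%.4g, %s (%d Dinkelbach iters)",
            seed,
            len(local.physical_nodes),
            len(sub.genes),
            sub.conductance,
            sub.est_fdr,
            sub.status,
            sub.dinkelbach_iterations,
        )
        results.append(sub)
        covered |= sub.genes
    return results
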