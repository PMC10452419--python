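"""MILP subnetwork search: instance coefficients, oracle equivalence, loop."""

import itertools

import numpy as np
import pytest

from multifdrnet import (
    GeneScoreTable,
    LayerNetwork,
    SeedList,
    build_instance,
    build_multiplex,
    conductance,
    detect_all,
    extract_local_graph,
    solve_subnetwork,
    walk_model,
)


def whole_network_local(M, walk, seed):
    """Local graph spanning the seed's whole component (K oversized)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_local_graph(walk, M, seed, K=4 * M.n_states)


def brute_force_optimum(M, walk, inst):
    """Enumerate all connected, seed-containing, FDR-feasible gene subsets
    and minimize the conductance evaluated independently on state nodes."""
    genes = inst.genes
    seed = inst.seed
    adj = {g: set() for g in genes}
    for (i, j) in inst.cut_coeffs:
        adj[genes[i]].add(genes[j])
        adj[genes[j]].add(genes[i])
    others = [g for g in genes if g != seed]
    best = None
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            P = set(combo) | {seed}
            mean_lfdr = np.mean([inst.lfdr[genes.index(g)] for g in P])
            if mean_lfdr > inst.B + 1e-12:
                continue
            # connectivity by traversal
            stack, seen = [seed], {seed}
            while stack:
                u = stack.pop()
                for v in adj[u] & P:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if seen != P:
                continue
            S = M.states_of(P)
            phi = conductance(M, walk, S) if len(S) < M.n_states else 0.0
            if best is None or phi < best[0] - 1e-15:
                best = (phi, P)
    return best


def random_small_instance(seed):
    """Random <= 12-gene two-layer instance plus a padding component so the
    candidate subnetwork never equals the whole state space."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    genes = [f"g{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                edges.add((genes[i], genes[j]))
    for i in range(n - 1):  # spanning path keeps the component whole
        edges.add((genes[i], genes[i + 1]))
    pad = [("padX", "padY")]
    layers = []
    for a in range(2):
        drop = {e for e in edges if rng.random() < 0.2} if a == 1 else set()
        kept = (edges - drop) | set(pad)
        layers.append(
            LayerNetwork.from_edge_list(f"L{a}", kept, isolated_genes=genes)
        )
    M = build_multiplex(layers)
    walk = walk_model(M)
    lfdr = {g: float(rng.uniform(0.0, 1.0) ** 2) for g in genes}
    seed_gene = min(lfdr, key=lfdr.get)
    lfdr[seed_gene] = min(lfdr[seed_gene], 0.05)
    B = float(rng.uniform(0.1, 0.4))
    table = GeneScoreTable.from_lfdr(lfdr | {"padX": 1.0, "padY": 1.0})
    local = whole_network_local(M, walk, seed_gene)
    inst = build_instance(local, M, walk, table, B)
    return M, walk, inst


class TestBuildInstance:
    def test_toy_coefficients_match_direct_conductance(self):
        l1 = LayerNetwork.from_edge_list("L1", [("A", "B")])
        l2 = LayerNetwork.from_edge_list("L2", [], isolated_genes=["A", "B"])
        M = build_multiplex([l1, l2])
        walk = walk_model(M)
        table = GeneScoreTable.from_lfdr({"A": 0.01, "B": 0.01})
        local = whole_network_local(M, walk, "A")
        inst = build_instance(local, M, walk, table, B=0.1)
        i, j = inst.genes.index("A"), inst.genes.index("B")
        assert inst.cut_coeffs[(min(i, j), max(i, j))] == pytest.approx(1.0)
        assert inst.boundary[i] == pytest.approx(0.0)
        assert inst.volume[i] == pytest.approx(3.0)  # deg(A1)=2 + deg(A2)=1
        x = np.zeros(2)
        x[i] = 1.0
        N, D = inst.cut_volume(x)
        assert N / D == pytest.approx(1 / 3)
        assert N / D == pytest.approx(
            conductance(M, walk, M.states_of(["A"]))
        )

    def test_boundary_bookkeeping_with_layer_weight(self):
        # gene B has edges to outside gene C in both layers; the weight-2
        # layer contributes 2 to B's boundary coefficient.  A local teleport
        # keeps the local graph at exactly {A, B} on this path topology.
        l1 = LayerNetwork.from_edge_list("L1", [("A", "B"), ("B", "C"), ("C", "D")])
        l2 = LayerNetwork.from_edge_list("L2", [("A", "B"), ("B", "C"), ("C", "D")],
                                         weight=2.0)
        M = build_multiplex([l1, l2])
        walk = walk_model(M)
        table = GeneScoreTable.from_lfdr({"A": 0.01, "B": 0.01, "C": 1.0, "D": 1.0})
        local = extract_local_graph(walk, M, "A", K=4, teleport=0.5)
        assert local.physical_nodes == frozenset({"A", "B"})
        inst = build_instance(local, M, walk, table, B=0.1)
        assert inst.boundary[inst.genes.index("B")] == pytest.approx(3.0)  # 1 + 2
        assert inst.boundary[inst.genes.index("A")] == pytest.approx(0.0)

    def test_full_component_has_zero_cut(self, clique_path_multiplex):
        M, walk, table, _ = clique_path_multiplex
        local = whole_network_local(M, walk, "C0")
        inst = build_instance(local, M, walk, table, B=0.99)
        x = np.ones(inst.n)
        N, _ = inst.cut_volume(x)
        assert N == pytest.approx(0.0)


class TestSolveSubnetwork:
    def test_planted_clique_recovered_exactly(self, clique_path_multiplex):
        M, walk, table, clique = clique_path_multiplex
        local = whole_network_local(M, walk, "C0")
        inst = build_instance(local, M, walk, table, B=0.1)
        sub = solve_subnetwork(inst, time_limit=120)
        assert sub.genes == frozenset(clique)
        assert sub.status == "optimal"
        assert sub.est_fdr <= 0.1 + 1e-12
        oracle_phi, oracle_set = brute_force_optimum(M, walk, inst)
        assert sub.genes == frozenset(oracle_set)
        assert sub.conductance == pytest.approx(oracle_phi, abs=1e-9)

    def test_hostile_neighbourhood_returns_singleton(self):
        l1 = LayerNetwork.from_edge_list("L1", [("S", "N1"), ("S", "N2"), ("N1", "N2")])
        M = build_multiplex([l1, LayerNetwork.from_edge_list(
            "L2", [("S", "N1"), ("S", "N2"), ("N1", "N2")])])
        walk = walk_model(M)
        table = GeneScoreTable.from_lfdr({"S": 0.01, "N1": 1.0, "N2": 1.0})
        local = whole_network_local(M, walk, "S")
        inst = build_instance(local, M, walk, table, B=0.1)
        sub = solve_subnetwork(inst, time_limit=60)
        assert sub.genes == frozenset({"S"})

    def test_infeasible_seed_raises(self, clique_path_multiplex):
        M, walk, table, _ = clique_path_multiplex
        local = whole_network_local(M, walk, "P3")  # lfdr 0.9 seed
        inst = build_instance(local, M, walk, table, B=0.1)
        with pytest.raises(ValueError, match="infeasible"):
            solve_subnetwork(inst)

    @pytest.mark.parametrize("batch", range(5))
    def test_matches_brute_force_on_random_instances(self, batch):
        """Dinkelbach MILP equals exhaustive enumeration (10 x 5 instances)."""
        for k in range(10):
            M, walk, inst = random_small_instance(5000 + 10 * batch + k)
            sub = solve_subnetwork(inst, time_limit=60)
            oracle_phi, _ = brute_force_optimum(M, walk, inst)
            assert sub.conductance == pytest.approx(oracle_phi, abs=1e-9), (
                f"instance seed {5000 + 10 * batch + k}"
            )
            assert sub.est_fdr <= inst.B + 1e-12
            assert inst.seed in sub.genes
            # connectivity by traversal over the physical adjacency
            adj = {g: set() for g in inst.genes}
            for (i, j) in inst.cut_coeffs:
                adj[inst.genes[i]].add(inst.genes[j])
                adj[inst.genes[j]].add(inst.genes[i])
            stack, seen = [inst.seed], {inst.seed}
            while stack:
                u = stack.pop()
                for v in adj[u] & sub.genes:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            assert seen == set(sub.genes)

    def test_conductance_fidelity_of_returned_subnetwork(self):
        M, walk, inst = random_small_instance(777)
        sub = solve_subnetwork(inst, time_limit=60)
        S = M.states_of(sub.genes)
        assert sub.conductance == pytest.approx(
            conductance(M, walk, S), abs=1e-9
        )

    def test_dinkelbach_iterations_bounded(self):
        for s in (901, 902, 903):
            _, _, inst = random_small_instance(s)
            sub = solve_subnetwork(inst, time_limit=60)
            assert 1 <= sub.dinkelbach_iterations <= 50


class TestDetectAll:
    def test_redundancy_skipping(self, clique_path_multiplex):
        M, walk, table, clique = clique_path_multiplex
        seeds = SeedList(seeds=["C0", "C3"], ordering_key={"C0": 1, "C3": 1})
        res = detect_all(M, walk, table, seeds, B=0.1, K=24, time_limit=60)
        assert len(res) == 1  # C3 was swallowed by C0's subnetwork
        assert res[0].genes == frozenset(clique)

    def test_disjoint_seeds_give_two_subnetworks(self):
        cl1 = [f"a{i}" for i in range(4)]
        cl2 = [f"b{i}" for i in range(4)]
        edges = (list(itertools.combinations(cl1, 2))
                 + list(itertools.combinations(cl2, 2))
                 + [("a0", "mid"), ("mid", "b0")])
        l1 = LayerNetwork.from_edge_list("L1", edges)
        l2 = LayerNetwork.from_edge_list("L2", edges)
        M = build_multiplex([l1, l2])
        walk = walk_model(M)
        lfdr = {g: 0.01 for g in cl1 + cl2} | {"mid": 1.0}
        table = GeneScoreTable.from_lfdr(lfdr)
        seeds = SeedList(seeds=["a0", "b0"], ordering_key={})
        res = detect_all(M, walk, table, seeds, B=0.1, K=16, time_limit=60)
        assert len(res) == 2
        assert res[0].genes == frozenset(cl1)
        assert res[1].genes == frozenset(cl2)

    def test_empty_seed_list(self, clique_path_multiplex):
        M, walk, table, _ = clique_path_multiplex
        res = detect_all(M, walk, table, SeedList(seeds=[], ordering_key={}))
        assert res == []
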