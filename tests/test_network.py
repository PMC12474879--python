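from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chronocomm.io_core import AsvTable, ChronoMeta, InputError
from chronocomm.network import (
    CorrNetwork,
    build_network,
    modules_zipi,
    robustness,
    sparcc,
    stage_subnetworks,
    topology,
)


def _table(x):
    x = np.asarray(x)
    return AsvTable(pd.DataFrame(x, index=[f"s{i}" for i in range(x.shape[0])],
                                 columns=[f"a{j}" for j in range(x.shape[1])]))


def _lognormal_counts(rng, n, d, depth=5000, cov=None):
    if cov is None:
        logab = rng.normal(0, 1, (n, d))
    else:
        logab = rng.multivariate_normal(np.zeros(d), cov, size=n)
    comp = np.exp(logab)
    comp /= comp.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, c) for c in comp])


class TestSparcc:
    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(0)
        t = _table(_lognormal_counts(rng, 20, 8))
        rho, p = sparcc(t, n_resample=5, n_boot=19, seed=1)
        r = rho.to_numpy()
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)

    def test_compositional_scale_invariance(self):
        rng = np.random.default_rng(1)
        counts = _lognormal_counts(rng, 30, 10)
        rho1, _ = sparcc(_table(counts), n_resample=20, n_boot=9, seed=2)
        rho2, _ = sparcc(_table(counts * 10), n_resample=20, n_boot=9, seed=2)
        iu = np.triu_indices(10, 1)
        diff = np.abs(rho1.to_numpy()[iu] - rho2.to_numpy()[iu])
        assert np.median(diff) < 0.1

    def test_too_few_taxa_rejected(self):
        t = _table([[1, 2, 3]] * 5)
        with pytest.raises(InputError, match="4 taxa"):
            sparcc(t, n_resample=2, n_boot=2, seed=0)


class TestBuildNetwork:
    def _mats(self, rho_vals, p_vals):
        ids = [f"a{j}" for j in range(rho_vals.shape[0])]
        return (pd.DataFrame(rho_vals, index=ids, columns=ids),
                pd.DataFrame(p_vals, index=ids, columns=ids))

    def test_threshold_is_strict(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.3   # exactly at the cutoff -> no edge
        rho[2, 3] = rho[3, 2] = 0.31
        p = np.full((4, 4), 0.01)
        net = build_network(*self._mats(rho, p))
        assert set(net.graph.edges) == {("a2", "a3")}

    def test_all_insignificant_gives_empty_network(self):
        rho = np.ones((4, 4))
        p = np.ones((4, 4))
        net = build_network(*self._mats(rho, p))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_edges_match_direct_enumeration(self):
        rng = np.random.default_rng(3)
        rho = rng.uniform(-1, 1, (4, 4))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        p = rng.uniform(0, 0.1, (4, 4))
        p = (p + p.T) / 2
        net = build_network(*self._mats(rho, p))
        expected = {
            tuple(sorted((f"a{i}", f"a{j}")))
            for i, j in combinations(range(4), 2)
            if abs(rho[i, j]) > 0.3 and p[i, j] < 0.05
        }
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected


class TestTopology:
    def test_star_closed_forms(self):
        g = nx.star_graph(4)  # center 0, leaves 1-4
        topo = topology(CorrNetwork(g))
        assert topo.loc[0, "degree"] == 4
        assert topo.loc[0, "betweenness"] == pytest.approx(6.0)
        assert topo.loc[1, "clustering"] == 0.0

    def test_triangle_clustering(self):
        topo = topology(CorrNetwork(nx.complete_graph(3)))
        assert (topo["clustering"] == 1.0).all()

    def test_matches_bfs_oracle_on_random_graph(self):
        g = nx.gnm_random_graph(6, 9, seed=4)
        topo = topology(CorrNetwork(g))

        # independent BFS implementation of closeness (within component)
        def bfs_dists(src):
            dist = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in g.neighbors(u):
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            return dist

        for node in g.nodes:
            dist = bfs_dists(node)
            reach = [d for v, d in dist.items() if v != node]
            expected = (len(reach) / sum(reach)) if reach and sum(reach) else 0.0
            assert topo.loc[node, "closeness"] == pytest.approx(expected)

    def test_degree_sum_is_twice_edges(self, ):
        g = nx.gnm_random_graph(10, 17, seed=5)
        topo = topology(CorrNetwork(g))
        assert topo["degree"].sum() == 2 * g.number_of_edges()


class TestZiPi:
    def _cliques_with_bridge(self, n_cliques=2):
        g = nx.Graph()
        for c in range(n_cliques):
            base = 10 * c
            for i, j in combinations(range(base, base + 5), 2):
                g.add_edge(i, j)
            g.add_edge(100, base)
        return g

    def test_bridge_across_three_cliques_is_connector(self):
        # degree 3 split over 3 foreign modules: Pi = 1 - 3*(1/3)^2 = 2/3
        res = modules_zipi(CorrNetwork(self._cliques_with_bridge(3)))
        assert res.loc[100, "Pi"] == pytest.approx(2 / 3)
        assert res.loc[100, "role"] == "connector"

    def test_two_clique_bridge_pi(self):
        res = modules_zipi(CorrNetwork(self._cliques_with_bridge(2)))
        assert res.loc[100, "Pi"] == pytest.approx(0.5)

    def test_internal_nodes_have_zero_pi(self):
        res = modules_zipi(CorrNetwork(self._cliques_with_bridge(2)))
        assert res.loc[1, "Pi"] == pytest.approx(0.0)

    def test_roles_partition_all_nodes(self):
        g = nx.gnm_random_graph(20, 40, seed=6)
        g.remove_nodes_from(list(nx.isolates(g)))
        res = modules_zipi(CorrNetwork(g))
        assert set(res["role"]).issubset(
            {"network_hub", "module_hub", "connector", "peripheral"}
        )
        assert len(res) == g.number_of_nodes()


class TestRobustness:
    def test_complete_graph_fully_retained(self):
        mean, sd = robustness(CorrNetwork(nx.complete_graph(6)), n_iter=50, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_edgeless_graph_scores_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        mean, _ = robustness(CorrNetwork(g), n_iter=20, seed=0)
        assert mean == 0.0

    def test_star_expectation_matches_enumeration(self):
        g = nx.star_graph(4)
        # enumerate all C(5,2)=10 removals of 2 nodes from 5
        shares = []
        nodes = list(g.nodes)
        for rm in combinations(nodes, 2):
            sub = g.subgraph([n for n in nodes if n not in rm])
            shares.append(
                sum(1 for v in sub.nodes if sub.degree(v) > 0) / sub.number_of_nodes()
            )
        expected = np.mean(shares)
        mean, _ = robustness(CorrNetwork(g), remove_frac=0.4, n_iter=4000, seed=1)
        assert mean == pytest.approx(expected, abs=0.03)


class TestStageSubnetworks:
    def test_connectivity_increases_with_duration(self):
        # common-factor loading grows with stage -> denser late networks
        rng = np.random.default_rng(7)
        stages, reps, d = 6, 6, 12
        rows, durs, labs = [], [], []
        for s in range(stages):
            lam = 2.5 * s / (stages - 1)
            signs = np.resize([1.0, -1.0], d)
            for r in range(reps):
                factor = rng.normal()
                logab = rng.normal(0, 1, d) + lam * factor * signs
                comp = np.exp(logab)
                comp /= comp.sum()
                rows.append(rng.multinomial(4000, comp))
                durs.append(float(s * 5))
                labs.append(f"g{s}")
        ids = [f"s{i}" for i in range(len(rows))]
        table = AsvTable(pd.DataFrame(rows, index=ids,
                                      columns=[f"a{j}" for j in range(d)]))
        meta = ChronoMeta(pd.DataFrame(
            {"duration": durs, "stage": labs,
             "replicate": list(range(1, reps + 1)) * stages}, index=ids))
        res = stage_subnetworks(table, meta, min_samples=4, seed=0,
                                n_resample=10, n_boot=49)
        assert res.attrs["degree_duration_rho"] > 0
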