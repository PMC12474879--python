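"""Compositionality-aware co-occurrence networks.

Correlations between taxa are estimated with the SparCC procedure: counts
are converted to fractions by Dirichlet posterior resampling, log-ratio
variances T_ij = var(log x_i / x_j) are computed, basis variances are
solved under a sparsity assumption, and the strongest correlated pairs
are iteratively excluded from the linear system. Edge significance comes
from a permutation bootstrap (each taxon's counts shuffled independently
across samples). Edges with |rho| > 0.3 and p < 0.05 form the network;
node roles follow the within-module connectivity Zi and among-module
participation Pi with the classical thresholds (module hubs Zi > 2.5,
connectors Pi > 0.62).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AsvTable, ChronoMeta, InputError
from .rarity import RarityLabels

logger = logging.getLogger(__name__)

RHO_MIN = 0.3
EDGE_ALPHA = 0.05
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# -- SparCC ---------------------------------------------------------------

def _basis_correlations(
    frac: np.ndarray,
    n_exclusion_iter: int,
    exclusion_thresh: float,
) -> np.ndarray:
    """One SparCC pass on a fraction matrix (samples x taxa)."""
    logf = np.log(frac)
    d = logf.shape[1]
    if d < 4:
        raise InputError("SparCC needs at least 4 taxa")
    # variation matrix
    var_mat = np.var(logf[:, :, None] - logf[:, None, :], axis=0, ddof=1)
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_vec = var_mat.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        omega2 = np.linalg.solve(m, t_vec)
        omega2 = np.maximum(omega2, 1e-12)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - var_mat) / (
            2 * np.outer(omega, omega)
        )
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0), omega

    rho, _ = solve()
    for _ in range(n_exclusion_iter):
        cand = np.abs(rho) * ~excluded
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_thresh:
            break
        # drop this pair's log-ratio variance from the linear system
        excluded[i, j] = excluded[j, i] = True
        for a, b in ((i, j), (j, i)):
            t_vec[a] -= var_mat[a, b]
            m[a, a] -= 1
        m[i, j] -= 1
        m[j, i] -= 1
        if np.any(np.diag(m) < 2):
            break
        rho, _ = solve()
    return rho


def _resampled_rho(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_resample: int,
    n_exclusion_iter: int,
    exclusion_thresh: float,
) -> np.ndarray:
    acc = np.zeros((counts.shape[1], counts.shape[1]))
    for _ in range(n_resample):
        frac = np.vstack([rng.dirichlet(row + 1) for row in counts])
        acc += _basis_correlations(frac, n_exclusion_iter, exclusion_thresh)
    return acc / n_resample


def sparcc(
    table: AsvTable,
    n_exclusion_iter: int = 20,
    exclusion_thresh: float = 0.1,
    n_resample: int = 100,
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SparCC correlation matrix and two-sided bootstrap p-values.

    The p-value null shuffles each taxon's counts independently across
    samples (destroying all correlation while keeping marginals); each of
    the `n_boot` shuffled datasets gets a single-resample SparCC pass, and
    p = (1 + #{|rho_null| >= |rho_obs|}) / (n_boot + 1).
    """
    counts = table.counts.to_numpy()
    ids = table.asv_ids
    rng = np.random.default_rng(seed)
    rho = _resampled_rho(counts, rng, n_resample, n_exclusion_iter, exclusion_thresh)
    exceed = np.zeros_like(rho)
    for _ in range(n_boot):
        shuffled = np.column_stack(
            [rng.permutation(counts[:, j]) for j in range(counts.shape[1])]
        )
        frac = np.vstack([rng.dirichlet(row + 1) for row in shuffled])
        rho_null = _basis_correlations(frac, n_exclusion_iter, exclusion_thresh)
        exceed += np.abs(rho_null) >= np.abs(rho)
    pvals = (1 + exceed) / (n_boot + 1)
    np.fill_diagonal(pvals, 0.0)
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(pvals, index=ids, columns=ids),
    )


# -- network construction -------------------------------------------------

@dataclass
class CorrNetwork:
    """Undirected significant-correlation network over ASVs."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_edge_share(self) -> float:
        if self.n_edges == 0:
            return float("nan")
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["rho"] > 0)
        return pos / self.n_edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(source=u, target=v, rho=d["rho"], p=d["p"],
                 sign="positive" if d["rho"] > 0 else "negative")
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"])

    def node_table(self) -> pd.DataFrame:
        rows = [dict(asv_id=n, **d) for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows).set_index("asv_id") if rows else pd.DataFrame()


def build_network(
    rho: pd.DataFrame,
    pvals: pd.DataFrame,
    rho_min: float = RHO_MIN,
    alpha: float = EDGE_ALPHA,
    labels: RarityLabels | None = None,
) -> CorrNetwork:
    """Retain edges with |rho| strictly above `rho_min` and p strictly below
    `alpha`; isolated nodes are dropped; node rarity classes attached."""
    if list(rho.index) != list(pvals.index):
        raise InputError("rho and p matrices must share their index")
    g = nx.Graph()
    ids = list(rho.index)
    r = rho.to_numpy()
    p = pvals.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(r[i, j]) > rho_min and p[i, j] < alpha:
                g.add_edge(ids[i], ids[j], rho=float(r[i, j]), p=float(p[i, j]))
    if labels is not None:
        cls = labels.class_of()
        for node in g.nodes:
            g.nodes[node]["rarity_class"] = cls.get(node, "unknown")
    return CorrNetwork(g)


# -- topology -------------------------------------------------------------

def topology(net: CorrNetwork) -> pd.DataFrame:
    """Degree, closeness (within components), betweenness and clustering."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise InputError("empty network")
    return pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree)),
            "closeness": pd.Series(nx.closeness_centrality(g, wf_improved=False)),
            "betweenness": pd.Series(nx.betweenness_centrality(g, normalized=False)),
            "clustering": pd.Series(nx.clustering(g)),
        }
    )


def modules_zipi(net: CorrNetwork, seed: int = 0, method: str = "greedy") -> pd.DataFrame:
    """Module assignment with within-module Zi and participation Pi.

    Modules from greedy modularity maximization (default) or Louvain
    (seeded). Zi is the z-score of a node's within-module degree among its
    module's members (0 with a degeneracy flag when the module has a single
    member or zero spread); Pi = 1 - sum_s (k_is / k_i)^2. Keystone classes:
    network hub (Zi > 2.5, Pi > 0.62), module hub (Zi > 2.5, Pi <= 0.62),
    connector (Zi <= 2.5, Pi > 0.62), peripheral otherwise.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise InputError("module detection needs at least one edge")
    if method == "greedy":
        communities = list(nx.algorithms.community.greedy_modularity_communities(g))
    elif method == "louvain":
        communities = list(nx.algorithms.community.louvain_communities(g, seed=seed))
    else:
        raise ValueError(f"unknown method {method!r}")
    module_of = {n: m for m, comm in enumerate(communities) for n in comm}
    k_within_all = {
        n: sum(1 for nb in g.neighbors(n) if module_of[nb] == module_of[n])
        for n in g.nodes
    }
    rows = {}
    for node in g.nodes:
        m = module_of[node]
        ks = np.array([k_within_all[n] for n in communities[m]], dtype=float)
        sd = ks.std(ddof=0)
        degenerate = len(ks) < 2 or sd == 0
        zi = 0.0 if degenerate else (k_within_all[node] - ks.mean()) / sd
        k_i = g.degree(node)
        shares = pd.Series([module_of[nb] for nb in g.neighbors(node)]).value_counts()
        pi = 1.0 - float(((shares / k_i) ** 2).sum()) if k_i > 0 else 0.0
        if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
            role = "network_hub"
        elif zi > ZI_THRESHOLD:
            role = "module_hub"
        elif pi > PI_THRESHOLD:
            role = "connector"
        else:
            role = "peripheral"
        rows[node] = dict(module=m, Zi=zi, Pi=pi, role=role, zi_degenerate=degenerate)
    return pd.DataFrame(rows).T.infer_objects()


def robustness(
    net: CorrNetwork,
    remove_frac: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "connected_share",
) -> tuple[float, float]:
    """Network robustness to random node removal.

    Per iteration, floor(remove_frac * n) nodes are removed uniformly at
    random; the retained share is the fraction of surviving nodes that
    still have at least one edge ("connected_share", default) or the
    relative size of the largest remaining component ("giant_share").
    Returns (mean, sd) over iterations.
    """
    g = net.graph
    nodes = list(g.nodes)
    n = len(nodes)
    if n < 4:
        raise InputError("robustness needs at least 4 nodes")
    n_remove = int(np.floor(remove_frac * n))
    rng = np.random.default_rng(seed)
    shares = np.empty(n_iter)
    for it in range(n_iter):
        keep_idx = rng.choice(n, size=n - n_remove, replace=False)
        sub = g.subgraph([nodes[i] for i in keep_idx])
        n_kept = sub.number_of_nodes()
        if n_kept == 0:
            shares[it] = 0.0
        elif mode == "connected_share":
            shares[it] = sum(1 for v in sub.nodes if sub.degree(v) > 0) / n_kept
        elif mode == "giant_share":
            comps = list(nx.connected_components(sub))
            shares[it] = max(len(c) for c in comps) / n_kept if comps else 0.0
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return float(shares.mean()), float(shares.std(ddof=1))


def stage_subnetworks(
    table: AsvTable,
    meta: ChronoMeta,
    labels: RarityLabels | None = None,
    min_samples: int = 4,
    seed: int = 0,
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Per-stage SparCC networks and mean node degree vs duration.

    Stages with fewer than `min_samples` samples are skipped; surviving
    stages are emitted with a low-n warning since per-stage correlation
    estimates rest on few replicates. Returns a per-stage summary (nodes,
    edges, mean degree, duration) with the rank correlation of mean degree
    against duration attached as DataFrame attrs.
    """
    meta.require_samples(table.sample_ids)
    stages = meta.stages().loc[table.sample_ids]
    rows = []
    for idx, (stage, members) in enumerate(stages.groupby(stages)):
        ids = list(members.index)
        if len(ids) < min_samples:
            logger.warning("stage %s: %d samples < %d; skipped", stage, len(ids), min_samples)
            continue
        logger.warning("stage %s: correlations estimated from only %d samples", stage, len(ids))
        sub = table.subset_samples(ids)
        keep = [a for a in sub.asv_ids if sub.counts[a].sum() > 0 and sub.counts[a].std() > 0]
        if len(keep) < 4:
            logger.warning("stage %s: fewer than 4 variable ASVs; skipped", stage)
            continue
        sub = sub.subset_asvs(keep)
        rho, p = sparcc(sub, seed=seed + idx, **sparcc_kwargs)
        net = build_network(rho, p, labels=labels)
        mean_degree = (2 * net.n_edges / net.n_nodes) if net.n_nodes else 0.0
        rows.append(
            dict(stage=stage, duration=float(meta.table.loc[ids, "duration"].mean()),
                 n_nodes=net.n_nodes, n_edges=net.n_edges, mean_degree=mean_degree)
        )
    out = pd.DataFrame(rows).set_index("stage")
    if len(out) >= 3:
        rho_trend = stats.spearmanr(out["duration"], out["mean_degree"])
        out.attrs["degree_duration_rho"] = float(rho_trend.statistic)
        out.attrs["degree_duration_p"] = float(rho_trend.pvalue)
    return out
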