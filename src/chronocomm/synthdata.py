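"""Synthetic chronosequence generator with known ground truth.

Emulates the statistical structure the analysis assumes: 11 restoration
stages (0-53 years) with 5 replicate samples each, a strongly skewed
(lognormal) regional species-abundance distribution, richness that ramps
up with restoration duration (saturating for abundant taxa, linear for
rare taxa), 17 positive-valued ecosystem functions co-varying with
duration and with abundant-taxon richness, and communities assembled
under controllable regimes. A birth-death phylogeny carries a Brownian
environmental-optimum trait, so selection regimes leave a phylogenetic
signature that the βNTI null model can detect; dispersal limitation is
emulated by per-sample multinomial drift with weak migration from the
pool; drift is plain multinomial sampling.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io_core import (
    FUNCTION_NAMES,
    AsvTable,
    ChronoMeta,
    FunctionTable,
    InputError,
    PhyloTree,
)

DEFAULT_DURATIONS = (0, 1, 3, 4, 5, 6, 11, 20, 23, 26, 53)

REGIMES = ("homogeneous_selection", "variable_selection", "dispersal_limitation", "drift")


@dataclass
class ScenarioConfig:
    """All knobs of the generator; defaults reproduce the study design."""

    durations: tuple[float, ...] = DEFAULT_DURATIONS
    replicates: int = 5
    pool_size: int = 2000
    depth: int = 20000
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.5
    birth_rate: float = 1.0
    death_rate: float = 0.5
    trait_sigma: float = 1.0
    trait_delta: float = 0.3      # Pagel-delta-style depth transform; <1 concentrates
                                  # trait evolution near the root (clade-structured niches)
    regime: str = "drift"
    selection_strength: float = 0.5   # niche width w; smaller = stronger selection
    env_range: float = 1.5            # stage-optimum span for variable selection
    drift_sigma: float = 3.0          # per-sample lognormal drift (dispersal limitation)
    migration_rate: float = 0.05
    abundant_pool_frac: float = 0.1   # top taxa treated as the "abundant" pool
    avail_abundant_base: float = 0.6  # saturating availability ramp for abundant taxa
    avail_abundant_tau: float = 5.0
    avail_rare_base: float = 0.15     # linear availability ramp for rare taxa
    avail_rare_final: float = 0.3
    function_duration_coef: float = 0.5
    function_richness_coef: float = 0.4
    function_noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.durations) != sorted(set(self.durations)):
            raise InputError("durations must be strictly increasing")
        if self.replicates < 2:
            raise InputError("need at least 2 replicates per stage")
        if self.pool_size < 50:
            raise InputError("pool size must be >= 50")
        if self.regime not in REGIMES:
            raise InputError(f"unknown regime {self.regime!r}")


#: Scenario presets used by the recovery tests: strong homogeneous or
#: variable selection, dispersal limitation, and neutral drift, at a pool
#: size small enough for per-pair null models.
PRESETS: dict[str, dict] = {
    "homogeneous_selection": dict(
        regime="homogeneous_selection", pool_size=150, depth=2000,
        selection_strength=0.25,
    ),
    "variable_selection": dict(
        regime="variable_selection", pool_size=150, depth=2000,
        selection_strength=0.25, env_range=2.5,
    ),
    "dispersal_limitation": dict(
        regime="dispersal_limitation", pool_size=150, depth=2000,
        drift_sigma=4.0, migration_rate=0.01,
    ),
    "drift": dict(regime="drift", pool_size=150, depth=2000),
}


def preset_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return ScenarioConfig(seed=seed, **params)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    rarity_class: pd.Series
    regime: str
    traits: pd.Series
    function_coefficients: pd.DataFrame
    config: ScenarioConfig


@dataclass
class ChronoDataset:
    table: AsvTable
    tree: PhyloTree
    meta: ChronoMeta
    functions: FunctionTable
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_tsv(outdir / "asv_table.tsv")
        self.meta.to_tsv(outdir / "metadata.tsv")
        self.functions.to_tsv(outdir / "functions.tsv")
        self.tree.to_newick(outdir / "tree.nwk")
        truth = {
            "regime": self.truth.regime,
            "rarity_class": self.truth.rarity_class.to_dict(),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.truth.config).items()},
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _simulate_tree(n_tips: int, birth: float, death: float, seed: int) -> PhyloTree:
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"ASV{i + 1:05d}"
    return PhyloTree(tree)


def _brownian_traits(
    tree: PhyloTree, sigma: float, rng: np.random.Generator, delta: float = 1.0
) -> pd.Series:
    """A heritable environmental-optimum trait evolving by Brownian motion.

    Node depths are transformed as depth**delta before computing increment
    variances; delta < 1 concentrates evolution near the root so deep
    clades acquire distinct optima and niches are phylogenetically
    conserved at every scale — the prerequisite for selection regimes to
    register in nearest-taxon statistics. Tip values are standardized.
    """
    depths: dict[int, float] = {}
    values: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[id(node)] = 0.0
            values[id(node)] = 0.0
        else:
            edge = node.edge.length or 0.0
            depths[id(node)] = depths[id(parent)] + edge
            var = max(depths[id(node)] ** delta - depths[id(parent)] ** delta, 0.0)
            values[id(node)] = values[id(parent)] + rng.normal(0.0, sigma * np.sqrt(var))
    tips = {leaf.taxon.label: values[id(leaf)] for leaf in tree.tree.leaf_node_iter()}
    s = pd.Series(tips)
    return (s - s.mean()) / s.std(ddof=0)


def generate_chronosequence(config: ScenarioConfig | None = None) -> ChronoDataset:
    """Generate one complete linked dataset (counts, tree, metadata,
    functions, ground truth) under the configured assembly regime."""
    cfg = config or ScenarioConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = dict(zip(("tree", "pool", "assembly", "functions"), ss.spawn(4)))

    tree = _simulate_tree(cfg.pool_size, cfg.birth_rate, cfg.death_rate,
                          int(seeds["tree"].generate_state(1)[0] % (2**31)))
    asv_ids = tree.tip_labels

    rng_pool = np.random.default_rng(seeds["pool"])
    pool = rng_pool.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cfg.pool_size)
    pool = pool / pool.sum()
    traits = _brownian_traits(tree, cfg.trait_sigma, rng_pool, cfg.trait_delta)

    n_abundant_pool = max(1, int(np.ceil(cfg.abundant_pool_frac * cfg.pool_size)))
    abundant_pool = np.zeros(cfg.pool_size, dtype=bool)
    abundant_pool[np.argsort(pool)[::-1][:n_abundant_pool]] = True

    rng_asm = np.random.default_rng(seeds["assembly"])
    t_max = max(cfg.durations)
    trait_vec = traits.loc[asv_ids].to_numpy()
    stage_env = np.linspace(-cfg.env_range, cfg.env_range, len(cfg.durations))

    sample_ids, rows, durations, stage_labels, reps = [], [], [], [], []
    for si, t in enumerate(cfg.durations):
        p_avail_ab = cfg.avail_abundant_base + (1 - cfg.avail_abundant_base) * (
            1 - np.exp(-t / cfg.avail_abundant_tau)
        )
        p_avail_rare = cfg.avail_rare_base + (
            cfg.avail_rare_final - cfg.avail_rare_base
        ) * (t / t_max)
        for rep in range(cfg.replicates):
            avail = np.where(
                abundant_pool,
                rng_asm.random(cfg.pool_size) < p_avail_ab,
                rng_asm.random(cfg.pool_size) < p_avail_rare,
            )
            w = pool * avail
            if cfg.regime == "homogeneous_selection":
                w = w * np.exp(-(trait_vec**2) / (2 * cfg.selection_strength**2))
            elif cfg.regime == "variable_selection":
                w = w * np.exp(
                    -((trait_vec - stage_env[si]) ** 2) / (2 * cfg.selection_strength**2)
                )
            elif cfg.regime == "dispersal_limitation":
                drift = w * np.exp(rng_asm.normal(0.0, cfg.drift_sigma, cfg.pool_size))
                drift = drift / drift.sum() if drift.sum() > 0 else drift
                base = pool / pool.sum()
                w = (1 - cfg.migration_rate) * drift + cfg.migration_rate * base
            if w.sum() == 0:
                raise InputError("infeasible availability: a sample drew no taxa")
            counts = rng_asm.multinomial(cfg.depth, w / w.sum())
            sid = f"S{si:02d}R{rep + 1}"
            sample_ids.append(sid)
            rows.append(counts)
            durations.append(float(t))
            stage_labels.append(f"stage{si:02d}")
            reps.append(rep + 1)

    table = AsvTable(pd.DataFrame(np.array(rows), index=sample_ids, columns=asv_ids))
    meta = ChronoMeta(
        pd.DataFrame(
            {"duration": durations, "stage": stage_labels, "replicate": reps},
            index=sample_ids,
        )
    )

    # ecosystem functions: log f = a * g(t) + b * z(abundant richness) + noise
    rng_fn = np.random.default_rng(seeds["functions"])
    g_t = 1 - np.exp(-np.array(durations) / 10.0)
    g_t = (g_t - g_t.mean()) / (g_t.std(ddof=0) or 1.0)
    abundant_ids = [a for a, flag in zip(asv_ids, abundant_pool) if flag]
    ab_rich = (table.counts[abundant_ids] > 0).sum(axis=1).to_numpy(dtype=float)
    ab_rich = (ab_rich - ab_rich.mean()) / (ab_rich.std(ddof=0) or 1.0)
    fn_rows = {}
    coef_rows = {}
    for fn in FUNCTION_NAMES:
        a = cfg.function_duration_coef * rng_fn.uniform(0.75, 1.25)
        b = cfg.function_richness_coef * rng_fn.uniform(0.75, 1.25)
        noise = rng_fn.normal(0.0, cfg.function_noise_sd, len(sample_ids))
        fn_rows[fn] = np.exp(a * g_t + b * ab_rich + noise)
        coef_rows[fn] = dict(duration=a, richness=b)
    functions = FunctionTable(pd.DataFrame(fn_rows, index=sample_ids))

    from .rarity import ABUNDANT_THRESHOLD, RARE_THRESHOLD

    true_class = pd.Series(
        np.where(pool > ABUNDANT_THRESHOLD, "abundant",
                 np.where(pool < RARE_THRESHOLD, "rare", "intermediate")),
        index=asv_ids,
    )
    truth = GroundTruth(
        rarity_class=true_class,
        regime=cfg.regime,
        traits=traits,
        function_coefficients=pd.DataFrame(coef_rows).T,
        config=cfg,
    )
    return ChronoDataset(table, tree, meta, functions, truth)


# -- path-model data ------------------------------------------------------

DEFAULT_PATH_EFFECTS: dict[tuple[str, str], float] = {
    ("duration", "cover"): 0.5,
    ("duration", "pH"): -0.5,
    ("duration", "EMF"): 0.3,
    ("cover", "richness"): 0.5,
    ("pH", "richness"): -0.3,
    ("cover", "EMF"): 0.2,
    ("pH", "EMF"): -0.2,
    ("richness", "EMF"): 0.3,
    ("richness", "degree"): 0.5,
    ("degree", "EMF"): 0.1,
}


def generate_pathmodel_data(
    effects: dict[tuple[str, str], float] | None = None,
    n: int = 55,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear-Gaussian data from a DAG with exact standardized effects.

    Noise variances are chosen from the implied covariance matrix so every
    variable has unit population variance; OLS on the z-scored sample then
    recovers the stated coefficients in expectation.
    """
    import networkx as nx

    effects = dict(DEFAULT_PATH_EFFECTS if effects is None else effects)
    g = nx.DiGraph()
    g.add_edges_from(effects.keys())
    if not nx.is_directed_acyclic_graph(g):
        raise InputError("effects must describe a DAG")
    order = list(nx.topological_sort(g))
    idx = {v: i for i, v in enumerate(order)}
    k = len(order)
    cov = np.zeros((k, k))
    noise_sd = np.zeros(k)
    beta = np.zeros((k, k))  # beta[parent, child]
    for (a, b), val in effects.items():
        beta[idx[a], idx[b]] = val
    for j, v in enumerate(order):
        parents = [idx[p] for p in g.predecessors(v)]
        if not parents:
            cov[j, j] = 1.0
            noise_sd[j] = 1.0
            continue
        bj = beta[parents, j]
        explained = bj @ cov[np.ix_(parents, parents)] @ bj
        if explained > 1.0 + 1e-9:
            raise InputError(f"effects into {v!r} imply variance > 1")
        noise_sd[j] = np.sqrt(max(1.0 - explained, 0.0))
        for i in range(j):
            cov[i, j] = cov[j, i] = beta[parents, j] @ cov[parents, i]
        cov[j, j] = 1.0
    rng = np.random.default_rng(seed)
    data = np.zeros((n, k))
    for j, v in enumerate(order):
        parents = [idx[p] for p in g.predecessors(v)]
        mean = data[:, parents] @ beta[parents, j] if parents else 0.0
        data[:, j] = mean + rng.normal(0.0, noise_sd[j], n)
    return pd.DataFrame(data, columns=order)
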