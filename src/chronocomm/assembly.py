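"""Null-model quantification of community assembly processes.

For every pair of communities two statistics are computed:

* βNTI — the standardized deviation of the observed abundance-weighted
  β-mean-nearest-taxon distance (βMNTD) from a null distribution obtained
  by shuffling taxa across the tips of the phylogeny. |βNTI| > 2 signals
  deterministic selection: βNTI > 2 variable selection (communities more
  phylogenetically divergent than expected), βNTI < -2 homogeneous
  selection.
* RC_bray — a Raup-Crick index on Bray-Curtis, rescaled to [-1, 1], from a
  null that assembles both communities probabilistically: taxa are drawn
  (without replacement, probability proportional to occupancy in the
  regional pool) up to the observed richness, then the observed number of
  individuals is allocated multinomially with probability proportional to
  pool relative abundance. Among pairs with |βNTI| < 2, RC > 0.95 indicates
  dispersal limitation, RC < -0.95 homogenizing dispersal, and |RC| <= 0.95
  the undominated bin (weak selection/dispersal, diversification, drift).

The five resulting process fractions sum to one.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .io_core import AsvTable, ChronoMeta, InputError, PhyloTree, relative_abundance

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def bmntd(
    fx: np.ndarray, fy: np.ndarray, dist: np.ndarray, weighted: bool = True
) -> float:
    """Abundance-weighted β-mean-nearest-taxon distance between two communities.

    `fx`, `fy` are abundance vectors over a shared taxon index; `dist` is the
    patristic distance matrix over that same index. For each taxon present in
    one community the distance to its nearest taxon in the other community is
    averaged, weighted by relative abundance (or equally when unweighted),
    and the two directions are averaged.
    """
    xi = np.nonzero(fx)[0]
    yi = np.nonzero(fy)[0]
    if len(xi) == 0 or len(yi) == 0:
        raise InputError("empty community in betaMNTD")
    sub = dist[np.ix_(xi, yi)]
    if weighted:
        wx = fx[xi] / fx[xi].sum()
        wy = fy[yi] / fy[yi].sum()
    else:
        wx = np.full(len(xi), 1 / len(xi))
        wy = np.full(len(yi), 1 / len(yi))
    return 0.5 * (wx @ sub.min(axis=1) + wy @ sub.min(axis=0))


def bnti(
    fx: np.ndarray,
    fy: np.ndarray,
    dist: np.ndarray,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[float, float, float, float]:
    """βNTI for one pair: (observed βMNTD, null mean, null sd, βNTI).

    The null relocates each community independently to a random set of
    tips (a taxa shuffle holding richness and the abundance vector fixed),
    so communities that share taxa — whose observed nearest-taxon
    distances are zero — register as phylogenetically closer than
    expected. A degenerate null (sd = 0) reports βNTI = 0.
    """
    obs = bmntd(fx, fy, dist, weighted)
    xi = np.nonzero(fx)[0]
    yi = np.nonzero(fy)[0]
    wx = fx[xi] / fx[xi].sum() if weighted else np.full(len(xi), 1 / len(xi))
    wy = fy[yi] / fy[yi].sum() if weighted else np.full(len(yi), 1 / len(yi))
    s = dist.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for k in range(n_null):
        px = rng.permutation(s)[: len(xi)]
        py = rng.permutation(s)[: len(yi)]
        sub = dist[np.ix_(px, py)]
        null[k] = 0.5 * (wx @ sub.min(axis=1) + wy @ sub.min(axis=0))
    mu, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate betaMNTD null (sd = 0); betaNTI set to 0")
        return obs, mu, 0.0, 0.0
    return obs, float(mu), float(sd), float((obs - mu) / sd)


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    return np.abs(x - y).sum() / (x.sum() + y.sum())


def _null_community(
    rng: np.random.Generator,
    richness: int,
    n_ind: int,
    occ_p: np.ndarray,
    ab_p: np.ndarray,
) -> np.ndarray:
    if n_ind < richness:
        raise InputError("fewer individuals than the target richness")
    chosen = rng.choice(len(occ_p), size=richness, replace=False, p=occ_p)
    probs = ab_p[chosen]
    out = np.zeros(len(occ_p))
    # every selected taxon receives one individual so the realized richness
    # equals the target; the remainder is allocated by pool abundance
    out[chosen] = 1 + rng.multinomial(n_ind - richness, probs / probs.sum())
    return out


def rc_bray(
    x: np.ndarray,
    y: np.ndarray,
    pool_occupancy: np.ndarray,
    pool_abundance: np.ndarray,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Bray-Curtis Raup-Crick index in [-1, 1] for one pair of count vectors.

    Both null communities of a pair are drawn independently; RC is the
    (tie-splitting) fraction of null Bray-Curtis values below the observed,
    rescaled to [-1, 1].
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    occ_p = np.asarray(pool_occupancy, float)
    if occ_p.sum() <= 0:
        raise InputError("pool occupancy sums to zero")
    occ_p = occ_p / occ_p.sum()
    n_avail = int(np.sum(occ_p > 0))
    rx, ry = int(np.sum(x > 0)), int(np.sum(y > 0))
    if max(rx, ry) > n_avail:
        raise InputError(
            f"observed richness {max(rx, ry)} exceeds pool richness {n_avail}"
        )
    obs = _bray(x, y)
    rng = np.random.default_rng(seed)
    less = eq = 0
    for _ in range(n_null):
        nx = _null_community(rng, rx, int(round(x.sum())), occ_p, pool_abundance)
        ny = _null_community(rng, ry, int(round(y.sum())), occ_p, pool_abundance)
        d = _bray(nx, ny)
        if d < obs:
            less += 1
        elif d == obs:
            eq += 1
    return float(2 * ((less + 0.5 * eq) / n_null) - 1)


def assign_process(bnti_value: float, rc_value: float) -> str:
    if bnti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(
    table: AsvTable,
    tree: PhyloTree,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """βMNTD, βNTI, RC_bray and assigned process for sample pairs.

    The regional pool for the Raup-Crick null is built from the analysed
    table itself (occupancy and mean relative abundance across all its
    samples), so subcommunity analyses automatically use subcommunity
    pools. Per-pair RNG streams derive from `seed` and the pair index, so
    results are independent of pair ordering or parallel scheduling.
    """
    samples = table.sample_ids
    nonzero = table.sample_sums() > 0
    if not nonzero.all():
        dropped = list(table.sample_sums()[~nonzero].index)
        logger.warning("dropping all-zero samples from assembly: %s", dropped)
        table = table.subset_samples([s for s in samples if nonzero[s]])
        samples = table.sample_ids
    tree.require_tips(table.asv_ids)
    dist = tree.patristic_matrix(table.asv_ids).to_numpy()
    ra = relative_abundance(table)
    counts = table.counts.to_numpy(dtype=float)
    pool_occ = (counts > 0).mean(axis=0)
    pool_ab = ra.mean(axis=0).to_numpy()
    ra_np = ra.to_numpy()
    pos = {s: i for i, s in enumerate(samples)}
    if pairs is None:
        pairs = list(combinations(samples, 2))
    rows = []
    for k, (si, sj) in enumerate(pairs):
        fx, fy = ra_np[pos[si]], ra_np[pos[sj]]
        obs, mu, sd, z = bnti(fx, fy, dist, n_null=n_null,
                              seed=_pair_seed(seed, k, 0), weighted=weighted)
        rc = rc_bray(counts[pos[si]], counts[pos[sj]], pool_occ, pool_ab,
                     n_null=n_null, seed=_pair_seed(seed, k, 1))
        rows.append(
            dict(sample_i=si, sample_j=sj, bmntd=obs, null_mean=mu, null_sd=sd,
                 bnti=z, rc=rc, process=assign_process(z, rc))
        )
    return pd.DataFrame(rows)


def _pair_seed(seed: int, pair_index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, pair_index, stream])


def partition_processes(pairs: pd.DataFrame) -> pd.Series:
    """Fractions of pairs assigned to each of the five processes (sum to 1)."""
    if len(pairs) == 0:
        raise InputError("no pairs to partition")
    frac = pairs["process"].value_counts(normalize=True)
    return frac.reindex(PROCESSES, fill_value=0.0)


def stochastic_fraction(fractions: pd.Series) -> float:
    """Combined share of the three stochastic bins."""
    return float(
        fractions[["dispersal_limitation", "homogenizing_dispersal", "undominated"]].sum()
    )


def stagewise_assembly(
    table: AsvTable,
    tree: PhyloTree,
    meta: ChronoMeta,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """Process fractions per restoration stage (within-stage sample pairs).

    Stages with fewer than two samples are skipped with a warning. Returns
    one row per stage with the five fractions and the number of pairs.
    """
    meta.require_samples(table.sample_ids)
    stages = meta.stages().loc[table.sample_ids]
    rows = []
    for stage_idx, (stage, members) in enumerate(stages.groupby(stages)):
        ids = list(members.index)
        if len(ids) < 2:
            logger.warning("stage %s has <2 samples; skipped", stage)
            continue
        sub = table.subset_samples(ids)
        keep = sub.sample_sums() > 0
        sub = sub.subset_samples([s for s in ids if keep[s]])
        if sub.n_samples < 2:
            logger.warning("stage %s has <2 non-empty samples; skipped", stage)
            continue
        res = pairwise_assembly(sub, tree, n_null=n_null,
                                seed=int((seed * 1000 + stage_idx) % (2**31)),
                                weighted=weighted)
        frac = partition_processes(res)
        row = {"stage": stage, "n_pairs": len(res),
               "duration": float(meta.table.loc[ids, "duration"].mean())}
        row.update(frac.to_dict())
        rows.append(row)
    if not rows:
        raise InputError("no stage had >=2 samples")
    return pd.DataFrame(rows).set_index("stage")
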