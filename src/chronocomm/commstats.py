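"""Distance-based community statistics.

Bray-Curtis dissimilarity and its Baselga decomposition into balanced
variation (species replacement) and abundance gradient (richness
difference) components, NMDS ordination, ANOSIM, SIMPER, the Mantel test,
and AIC-based selection among richness-vs-duration regression models
(linear, quadratic, logarithmic, and a monomolecular "restoration" curve
y = a(1 - exp(-k t)) + c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.manifold import MDS

from .io_core import AsvTable, InputError


# -- distances ------------------------------------------------------------

def _as_matrix(table: AsvTable | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, AsvTable):
        return table.counts.to_numpy(dtype=float), table.sample_ids
    return table.to_numpy(dtype=float), list(table.index)


def bray_curtis(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    x, ids = _as_matrix(table)
    sums = x.sum(axis=1)
    if np.any(sums == 0):
        raise InputError(
            f"all-zero samples: {[ids[i] for i in np.nonzero(sums == 0)[0]]}"
        )
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = sums[:, None] + sums[None, :]
    return pd.DataFrame(num / den, index=ids, columns=ids)


@dataclass
class BetaPartition:
    """Baselga decomposition of Bray-Curtis into balanced + gradient parts."""

    pairs: pd.DataFrame      # columns: sample_i, sample_j, total, balanced, gradient
    summary: pd.Series       # mean similarity / turnover share / richness share

    def shares(self) -> pd.Series:
        return self.summary


def partition_beta(table: AsvTable | pd.DataFrame) -> BetaPartition:
    """Per-pair balanced-variation and abundance-gradient components.

    With A = sum of per-taxon minima and B, C the sample-specific
    remainders: total d = (B+C)/(2A+B+C), balanced = min(B,C)/(A+min(B,C)),
    gradient = d - balanced. The dataset summary expresses mean similarity,
    mean balanced share and mean gradient share of 1 (so the three sum to 1).
    """
    x, ids = _as_matrix(table)
    if np.any(x.sum(axis=1) == 0):
        raise InputError("all-zero samples")
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        a = np.minimum(x[i], x[j]).sum()
        b = (x[i] - np.minimum(x[i], x[j])).sum()
        c = (x[j] - np.minimum(x[i], x[j])).sum()
        total = (b + c) / (2 * a + b + c)
        bal = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
        rows.append((ids[i], ids[j], total, bal, total - bal))
    pairs = pd.DataFrame(rows, columns=["sample_i", "sample_j", "total", "balanced", "gradient"])
    summary = pd.Series(
        {
            "similarity": 1 - pairs["total"].mean(),
            "balanced_share": pairs["balanced"].mean(),
            "gradient_share": pairs["gradient"].mean(),
        }
    )
    return BetaPartition(pairs, summary)


# -- ordination -----------------------------------------------------------

def nmds(
    dist: pd.DataFrame, k: int = 2, seed: int = 0, restarts: int = 20
) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS of a distance matrix; returns coordinates and stress-1."""
    if dist.shape[0] < k + 1:
        raise InputError(f"NMDS with k={k} needs at least {k + 1} samples")
    d = dist.to_numpy()
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=300,
        eps=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(d)
    return (
        pd.DataFrame(coords, index=dist.index, columns=[f"NMDS{i+1}" for i in range(k)]),
        float(model.stress_),
    )


# -- permutation tests ----------------------------------------------------

def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return (1 + int(np.sum(null >= obs))) / (len(null) + 1)


def anosim(
    dist: pd.DataFrame, groups: pd.Series, nperm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """ANOSIM R and permutation p-value for grouped samples.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    over ranks of all pairwise distances; p is the +1-corrected fraction of
    label permutations with R at least the observed.
    """
    g = np.asarray(groups.loc[dist.index])
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise InputError("ANOSIM needs >=2 groups with >=2 samples each")
    n = len(g)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist.to_numpy()[iu])
    denom = n * (n - 1) / 4

    def r_stat(gv: np.ndarray) -> float:
        within = gv[iu[0]] == gv[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(g)
    rng = np.random.default_rng(seed)
    null = np.array([r_stat(rng.permutation(g)) for _ in range(nperm)])
    return float(r_obs), _perm_pvalue(r_obs, null)


def simper(
    table: AsvTable, groups: pd.Series
) -> pd.DataFrame:
    """Per-ASV mean contribution to between-group Bray-Curtis dissimilarity.

    For a pair (x, y), ASV i contributes |x_i - y_i| / sum_j (x_j + y_j);
    contributions sum exactly to the pair's Bray-Curtis distance. Returned
    contributions are averaged over all between-group pairs, with each ASV's
    share of the mean dissimilarity.
    """
    g = np.asarray(groups.loc[table.sample_ids])
    if len(np.unique(g)) < 2:
        raise InputError("SIMPER needs at least 2 groups")
    x, _ = _as_matrix(table)
    if np.any(x.sum(axis=1) == 0):
        raise InputError("all-zero samples")
    contribs = []
    for i, j in combinations(range(len(g)), 2):
        if g[i] == g[j]:
            continue
        contribs.append(np.abs(x[i] - x[j]) / (x[i].sum() + x[j].sum()))
    if not contribs:
        raise InputError("no between-group pairs")
    mean_contrib = np.mean(contribs, axis=0)
    out = pd.DataFrame(
        {"contribution": mean_contrib, "share": mean_contrib / mean_contrib.sum()},
        index=table.counts.columns,
    )
    return out.sort_values("contribution", ascending=False)


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    method: str = "spearman",
    nperm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples.

    One matrix's rows/columns are permuted jointly; p is one-sided
    (correlation at least as large as observed), +1 corrected.
    """
    if list(d1.index) != list(d2.index):
        if set(d1.index) != set(d2.index):
            raise InputError("Mantel matrices must cover the same samples")
        d2 = d2.loc[d1.index, d1.index]
    corr = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    a, b = d1.to_numpy(), d2.to_numpy()
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise InputError("zero-variance distance matrix in Mantel test")
    r_obs = float(corr(va, vb).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(nperm)
    for k in range(nperm):
        perm = rng.permutation(n)
        null[k] = corr(va, b[np.ix_(perm, perm)][iu]).statistic
    return r_obs, _perm_pvalue(r_obs, null)


# -- regression model selection -------------------------------------------

def _aic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * n_params


def fit_richness_models(
    durations: np.ndarray | pd.Series, richness: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Fit the four candidate richness-vs-duration models and rank by AIC.

    Candidates: linear a+bt, quadratic a+bt+ct^2, logarithmic a+b ln(t+1),
    and the restoration curve y = a(1 - exp(-k t)) + c (a, k > 0) fitted by
    nonlinear least squares. Gaussian AIC = n ln(RSS/n) + 2p; the row order
    is ascending AIC, so the first row is the selected model.
    """
    t = np.asarray(durations, dtype=float)
    y = np.asarray(richness, dtype=float)
    if len(t) < 5:
        raise InputError("model selection needs at least 5 points")
    n = len(t)
    results = {}

    for name, design, p in (
        ("linear", np.column_stack([np.ones(n), t]), 2),
        ("quadratic", np.column_stack([np.ones(n), t, t**2]), 3),
        ("logarithmic", np.column_stack([np.ones(n), np.log(t + 1)]), 2),
    ):
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((y - design @ coef) ** 2).sum())
        results[name] = dict(aic=_aic(rss, n, p), rss=rss, params=tuple(coef))

    def resto(tt, a, k, c):
        return a * (1 - np.exp(-k * tt)) + c

    try:
        k0 = 1.0 / max(np.median(t), 1e-6)
        p0 = (max(y.max() - y.min(), 1e-6), k0, y.min())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                resto, t, y, p0=p0,
                bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        rss = float(((y - resto(t, *popt)) ** 2).sum())
        results["restoration"] = dict(aic=_aic(rss, n, 3), rss=rss, params=tuple(popt))
    except RuntimeError:
        warnings.warn("restoration model did not converge; excluded from selection")

    out = pd.DataFrame(results).T.sort_values("aic")
    out.index.name = "model"
    return out
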