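"""Niche-breadth metrics and the rank-based group comparison used throughout.

Levins' index B = 1 / sum(p_i^2) measures how evenly an ASV spreads its
reads over resource states (default: the restoration-stage means, reducing
replicate noise); the tolerance index measures the abundance-weighted
spread of an ASV's occupied samples in the principal-component space of
the standardized ecosystem-function matrix (the OMI "Tol" statistic).
Group differences are tested with Kruskal-Wallis followed by Dunn's
post-hoc z tests under Bonferroni correction, summarized as a compact
letter display.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AsvTable, ChronoMeta, FunctionTable, InputError, relative_abundance

logger = logging.getLogger(__name__)


def levins_breadth(
    table: AsvTable,
    meta: ChronoMeta | None = None,
    by_stage: bool = True,
) -> pd.DataFrame:
    """Levins' niche breadth B and its normalization B_N per ASV.

    Resource states are the restoration stages (mean of replicate
    proportions per stage) when `by_stage`, otherwise the individual
    samples. B = 1/sum p_i^2 with p_i the ASV's proportion of use of state
    i; B is 1 for a single-state specialist and N for perfectly even use
    of N states; B_N = (B-1)/(N-1).
    """
    ra = relative_abundance(table)
    if by_stage:
        if meta is None:
            raise InputError("stage mode requires metadata")
        meta.require_samples(table.sample_ids)
        stages = meta.stages().loc[table.sample_ids]
        use = ra.groupby(stages).mean()
    else:
        use = ra
    n_states = use.shape[0]
    if n_states < 2:
        raise InputError("niche breadth undefined with a single resource state")
    totals = use.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        logger.warning("%d ASVs absent everywhere dropped from Levins", int((~keep).sum()))
    p = use.loc[:, keep].div(totals[keep], axis=1)
    b = 1.0 / (p**2).sum(axis=0)
    return pd.DataFrame({"B": b, "B_N": (b - 1) / (n_states - 1)})


def levins_breadth_binned(
    table: AsvTable, functions: FunctionTable, n_bins: int = 5
) -> pd.DataFrame:
    """Levins' breadth with resource states defined by binned functions.

    Each function is split into `n_bins` equal-frequency bins of samples;
    breadth is computed per function and averaged across functions,
    treating each measured function as an environmental axis.
    """
    values = functions.table.loc[table.sample_ids]
    ra = relative_abundance(table)
    per_fn = []
    for fn in values.columns:
        bins = pd.qcut(values[fn].rank(method="first"), n_bins, labels=False)
        use = ra.groupby(bins.to_numpy()).mean()
        totals = use.sum(axis=0)
        p = use.div(totals.where(totals > 0), axis=1)
        b_fn = 1.0 / (p**2).sum(axis=0)
        per_fn.append(b_fn.where(totals > 0))
    b = pd.concat(per_fn, axis=1).mean(axis=1)
    return pd.DataFrame({"B": b, "B_N": (b - 1) / (n_bins - 1)})


def _function_scores(functions: FunctionTable) -> pd.DataFrame:
    """Sample coordinates on the principal axes of the z-scored functions."""
    x = functions.table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning(
            "dropping constant function columns: %s",
            [functions.table.columns[i] for i in np.nonzero(~keep)[0]],
        )
    x = x[:, keep]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    cov = np.atleast_2d(np.cov(z, rowvar=False))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    scores = z @ evecs[:, pos]
    return pd.DataFrame(scores, index=functions.table.index)


def tolerance_index(table: AsvTable, functions: FunctionTable) -> pd.Series:
    """OMI-style tolerance per ASV.

    Sample scores come from the PCA of the standardized function matrix;
    an ASV's position is its abundance-weighted mean score and its
    tolerance the abundance-weighted mean squared distance of its occupied
    samples from that position. Zero for ASVs present in one sample;
    invariant to uniform scaling of the ASV's abundances.
    """
    scores = _function_scores(functions).loc[table.sample_ids].to_numpy()
    counts = table.counts.to_numpy(dtype=float)
    tol = np.zeros(table.n_asvs)
    for j in range(table.n_asvs):
        w = counts[:, j]
        if w.sum() == 0:
            tol[j] = np.nan
            continue
        w = w / w.sum()
        m = w @ scores
        tol[j] = w @ ((scores - m) ** 2).sum(axis=1)
    return pd.Series(tol, index=table.counts.columns, name="tolerance")


def kruskal_dunn(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> dict:
    """Kruskal-Wallis H with Dunn's post-hoc test (Bonferroni correction).

    Returns the H statistic and global p, a per-pair table of Dunn z and
    adjusted p, and a compact letter display (groups sharing a letter do
    not differ at `alpha`).
    """
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in names]
    if any(len(s) == 0 for s in samples):
        raise InputError("empty group")
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    # Dunn: z from mean ranks of the pooled data, tie-corrected
    pooled = df["value"].to_numpy()
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    mean_rank = {g: ranks[(df["group"] == g).to_numpy()].mean() for g in names}
    sizes = {g: int((df["group"] == g).sum()) for g in names}
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt((n * (n + 1) / 12 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        praw = 2 * stats.norm.sf(abs(z))
        rows.append(dict(group_a=a, group_b=b, z=z, p_raw=praw,
                         p_adj=min(1.0, praw * len(pairs))))
    dunn = pd.DataFrame(rows)
    letters = _compact_letters(names, dunn, alpha)
    return {"H": float(h), "p": float(p), "dunn": dunn, "letters": letters}


def _compact_letters(names: list[str], dunn: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Greedy compact letter display from pairwise adjusted p-values."""
    differ = {
        frozenset((r.group_a, r.group_b)) for r in dunn.itertuples() if r.p_adj < alpha
    }
    letter_groups: list[set[str]] = []
    for g in names:
        placed = False
        for lg in letter_groups:
            if all(frozenset((g, other)) not in differ for other in lg):
                lg.add(g)
                placed = True
        if not placed:
            letter_groups.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for i, lg in enumerate(letter_groups):
        for g in lg:
            out[g] += alphabet[i]
    return out
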