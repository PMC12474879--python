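"""Rarity classification of ASVs and multivariate cutoff level analysis.

Taxa are split into abundant / intermediate / rare classes by their mean
relative abundance across samples. The thresholds default to 0.028% and
0.002%, the plateau values read off a multivariate cutoff level analysis
(MultiCoLA) profile: low-count ASVs are truncated at increasing fractions
of total sequences, and the truncated datasets are compared to the
original by Spearman correlation of Bray-Curtis distances and Procrustes
correlation of NMDS ordinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes

from .io_core import AsvTable, ChronoMeta, InputError, relative_abundance

ABUNDANT_THRESHOLD = 2.8e-4  # mean relative abundance above -> abundant
RARE_THRESHOLD = 2e-5        # mean relative abundance below -> rare

CLASSES = ("abundant", "intermediate", "rare")


@dataclass
class RarityLabels:
    """Per-ASV rarity class with its mean relative abundance and occupancy."""

    table: pd.DataFrame  # index asv_id; columns: rarity_class, mean_relabund, occupancy

    def asvs_in(self, rarity_class: str) -> list[str]:
        if rarity_class not in CLASSES:
            raise ValueError(f"unknown class {rarity_class!r}")
        sub = self.table[self.table["rarity_class"] == rarity_class]
        return list(sub.index)

    def class_of(self) -> pd.Series:
        return self.table["rarity_class"]

    def class_counts(self) -> pd.Series:
        return self.table["rarity_class"].value_counts().reindex(CLASSES, fill_value=0)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RarityLabels":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def mean_relative_abundance(table: AsvTable, mode: str = "per_sample") -> pd.Series:
    """Mean relative abundance per ASV.

    mode="per_sample": mean of per-sample proportions (default; identical to
    the pooled mode when samples are rarefied to a common depth).
    mode="pooled": ASV total count over grand total.
    """
    if mode == "per_sample":
        return relative_abundance(table).mean(axis=0)
    if mode == "pooled":
        totals = table.counts.sum(axis=0)
        return totals / totals.sum()
    raise ValueError(f"unknown mode {mode!r}")


def occupancy(table: AsvTable) -> pd.Series:
    """Fraction of samples in which each ASV is present (count > 0).

    ASVs with zero total count are excluded (a warning is logged since they
    carry no occupancy information).
    """
    present = (table.counts > 0).sum(axis=0)
    totals = table.counts.sum(axis=0)
    keep = totals > 0
    if (~keep).any():
        import logging

        logging.getLogger(__name__).warning(
            "%d ASVs with zero total count excluded from occupancy", int((~keep).sum())
        )
    return (present[keep] / table.n_samples).astype(float)


def classify_taxa(
    table: AsvTable,
    abundant_thresh: float = ABUNDANT_THRESHOLD,
    rare_thresh: float = RARE_THRESHOLD,
    mode: str = "per_sample",
) -> RarityLabels:
    """Classify every ASV as abundant, intermediate or rare.

    Strict inequalities: mean relative abundance > `abundant_thresh` is
    abundant, < `rare_thresh` is rare, anything else (boundaries included)
    is intermediate.
    """
    if not (0 < rare_thresh < abundant_thresh):
        raise InputError("thresholds must satisfy 0 < rare < abundant")
    mra = mean_relative_abundance(table, mode=mode)
    cls = np.where(
        mra > abundant_thresh, "abundant", np.where(mra < rare_thresh, "rare", "intermediate")
    )
    present = (table.counts > 0).sum(axis=0) / table.n_samples
    out = pd.DataFrame(
        {"rarity_class": cls, "mean_relabund": mra, "occupancy": present.astype(float)},
        index=table.counts.columns,
    )
    return RarityLabels(out)


def class_shares(table: AsvTable, labels: RarityLabels) -> pd.DataFrame:
    """ASV-count and sequence shares per rarity class (each column sums to 1)."""
    totals = table.counts.sum(axis=0)
    rows = {}
    for c in CLASSES:
        asvs = labels.asvs_in(c)
        rows[c] = {
            "asv_share": len(asvs) / table.n_asvs,
            "sequence_share": totals[asvs].sum() / totals.sum(),
        }
    return pd.DataFrame(rows).T


def temporal_response(
    table: AsvTable, meta: ChronoMeta, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify each ASV's relative-abundance trend over restoration duration.

    Pearson correlation of per-sample relative abundance against duration;
    positive/negative when significant at `alpha`, otherwise stable.
    Zero-variance ASVs are stable with r recorded as 0.
    """
    meta.require_samples(table.sample_ids)
    t = meta.durations().loc[table.sample_ids].to_numpy(dtype=float)
    if len(np.unique(t)) < 3:
        raise InputError("need at least 3 distinct durations")
    ra = relative_abundance(table).to_numpy()
    n = len(t)
    tc = t - t.mean()
    x = ra - ra.mean(axis=0)
    sx = np.sqrt((x**2).sum(axis=0))
    st = np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * tc[:, None]).sum(axis=0) / (sx * st)
    zero_var = sx == 0
    r = np.where(zero_var, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(zero_var, 1.0, p)
    response = np.where(
        (p < alpha) & (r > 0), "positive", np.where((p < alpha) & (r < 0), "negative", "stable")
    )
    return pd.DataFrame(
        {"r": r, "p": p, "response": response}, index=table.counts.columns
    )


# -- MultiCoLA ------------------------------------------------------------

def procrustes_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes correlation sqrt(1 - m^2) of two configurations."""
    _, _, disparity = _procrustes(np.asarray(x, float), np.asarray(y, float))
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def _lower_triangle(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy()
    iu = np.tril_indices(a.shape[0], k=-1)
    return a[iu]


def _truncation_order(table: AsvTable) -> pd.Index:
    """ASVs ranked ascending by total count, ties broken by id."""
    totals = table.counts.sum(axis=0)
    order = sorted(totals.index, key=lambda a: (totals[a], a))
    return pd.Index(order)


def multicola_profile(
    table: AsvTable,
    cutoffs: list[float] | None = None,
    seed: int = 0,
    nmds_restarts: int = 4,
) -> pd.DataFrame:
    """Truncation profile of community-structure conservation.

    For each cutoff fraction of total sequences, low-count ASVs making up
    that fraction are split off: the "removed" dataset keeps the dominant
    remainder, the "retained" dataset keeps only the truncated rare tail.
    Each is compared to the full dataset by Spearman rho over lower-triangle
    Bray-Curtis distances and by Procrustes correlation of 2-D NMDS
    configurations. Cutoffs whose truncated dataset contains an all-zero
    sample are flagged rather than dropped.
    """
    from .commstats import bray_curtis, nmds

    if table.n_samples < 3:
        raise InputError("MultiCoLA needs at least 3 samples")
    if cutoffs is None:
        cutoffs = [c / 100 for c in range(1, 96)]
    for c in cutoffs:
        if not 0 < c < 1:
            raise InputError(f"cutoff {c} outside (0, 1)")

    order = _truncation_order(table)
    totals = table.counts.sum(axis=0).loc[order]
    cum = totals.cumsum() / totals.sum()

    d_full = bray_curtis(table)
    full_tri = _lower_triangle(d_full)
    coords_full, _ = nmds(d_full, seed=seed, restarts=nmds_restarts)

    records = []
    for c in cutoffs:
        # rare tail = longest ascending-count prefix holding <= c of sequences
        n_rare = int(np.searchsorted(cum.to_numpy(), c, side="right"))
        n_rare = min(n_rare, len(order) - 1)
        rare_ids = order[:n_rare]
        kept_ids = order[n_rare:]
        for subset, ids in (("removed", kept_ids), ("retained", rare_ids)):
            sub = table.subset_asvs(ids)
            flagged = bool((sub.sample_sums() == 0).any())
            if flagged:
                records.append(
                    dict(cutoff=c, subset=subset, rho=np.nan, procrustes=np.nan,
                         flagged=True)
                )
                continue
            d_sub = bray_curtis(sub)
            rho = stats.spearmanr(full_tri, _lower_triangle(d_sub)).statistic
            if np.isnan(rho):  # zero-variance distances (identity truncation)
                rho = 1.0
            coords_sub, _ = nmds(d_sub, seed=seed, restarts=nmds_restarts)
            pc = procrustes_correlation(coords_full, coords_sub)
            records.append(
                dict(cutoff=c, subset=subset, rho=float(rho), procrustes=pc,
                     flagged=False)
            )
    return pd.DataFrame.from_records(records)
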