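"""Ecosystem multifunctionality indices and function-association analyses.

EMF is the averaging index: each function is log10-transformed, z-scored
across samples, and the 17 z-scores averaged per sample. Sub-indices
average subsets: PPI over the plant-productivity functions, DRI over the
decomposition-rate functions, SNPI over the soil-nutrient-pool functions.
The module also provides richness-EMF regressions per rarity class,
per-ASV function-association profiles, degree-vs-|r| regressions for
network nodes, and the Mantel link between composition and EMF distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AsvTable, FunctionTable, InputError, relative_abundance
from .rarity import CLASSES, RarityLabels

logger = logging.getLogger(__name__)

FUNCTION_GROUPS: dict[str, tuple[str, ...]] = {
    "PPI": ("AGB", "PC", "PN", "PP"),
    "DRI": ("DNA", "Suc", "b-Glu", "Cel", "Ure", "ALP", "Cat"),
    "SNPI": ("SOC", "NH4", "NO3", "STN", "SAP", "STP"),
}


def function_zscores(functions: FunctionTable) -> pd.DataFrame:
    """Per-function z-scores of log10 values (zero-handling by half-minimum offset)."""
    raw = functions.table.copy()
    for fn in raw.columns:
        col = raw[fn]
        if (col < 0).any():
            raise InputError(f"negative values in function {fn!r}")
        if (col == 0).any():
            positive = col[col > 0]
            if positive.empty:
                raise InputError(f"function {fn!r} is all zeros")
            offset = positive.min() / 2
            logger.info("function %s: %d zeros offset by %.3g", fn, int((col == 0).sum()), offset)
            raw[fn] = col + offset
    logged = np.log10(raw)
    sd = logged.std(ddof=1)
    if (sd == 0).any():
        raise InputError(f"constant functions: {list(sd[sd == 0].index)}")
    return (logged - logged.mean()) / sd


def compute_emf(functions: FunctionTable) -> pd.DataFrame:
    """Per-sample EMF plus the PPI / DRI / SNPI sub-indices."""
    z = function_zscores(functions)
    out = pd.DataFrame({"EMF": z.mean(axis=1)})
    for name, members in FUNCTION_GROUPS.items():
        present = [m for m in members if m in z.columns]
        if len(present) != len(members):
            missing = sorted(set(members) - set(present))
            raise InputError(f"{name} functions missing from table: {missing}")
        out[name] = z[present].mean(axis=1)
    return out


def class_richness(table: AsvTable, labels: RarityLabels) -> pd.DataFrame:
    """Observed per-sample ASV richness within each rarity class."""
    out = {}
    for c in CLASSES:
        asvs = labels.asvs_in(c)
        out[c] = (table.counts[asvs] > 0).sum(axis=1) if asvs else 0
    out["all"] = (table.counts > 0).sum(axis=1)
    return pd.DataFrame(out)


def richness_emf_regression(
    richness: pd.DataFrame, emf: pd.Series
) -> pd.DataFrame:
    """OLS of EMF on per-class richness; slope, r, p and significance flag."""
    if len(emf) < 5:
        raise InputError("regression needs at least 5 samples")
    rows = {}
    for col in richness.columns:
        x = richness[col].loc[emf.index].to_numpy(dtype=float)
        if x.std() == 0:
            rows[col] = dict(slope=np.nan, intercept=np.nan, r=np.nan, p=np.nan,
                             significant=False, flagged=True)
            continue
        fit = stats.linregress(x, emf.to_numpy())
        rows[col] = dict(slope=fit.slope, intercept=fit.intercept, r=fit.rvalue,
                         p=fit.pvalue, significant=fit.pvalue <= 0.05, flagged=False)
    return pd.DataFrame(rows).T


def asv_function_associations(
    table: AsvTable,
    functions: FunctionTable,
    emf: pd.Series,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-ASV Pearson associations with each function and with EMF.

    Returns per ASV the number k of individually significant functions
    (raw alpha by default; Benjamini-Hochberg within ASV when `fdr`) and
    |r| against EMF. Constant ASVs get k = 0 and undefined correlations.
    """
    ra = relative_abundance(table)
    z = function_zscores(functions).loc[table.sample_ids]
    n = table.n_samples
    x = ra.to_numpy()
    xc = x - x.mean(axis=0)
    sx = xc.std(axis=0, ddof=1) * np.sqrt(n - 1)
    fz = z.to_numpy()
    fc = fz - fz.mean(axis=0)
    sf = fc.std(axis=0, ddof=1) * np.sqrt(n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ fc) / np.outer(sx, sf)
    r = np.clip(r, -1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(r), 1.0, p)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        for i in range(p.shape[0]):
            p[i] = multipletests(p[i], method="fdr_bh")[1]
    k = (p < alpha).sum(axis=1)
    emf_v = emf.loc[table.sample_ids].to_numpy()
    ec = emf_v - emf_v.mean()
    se = np.sqrt((ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_emf = (xc.T @ ec) / (sx * se)
    out = pd.DataFrame(
        {"k_significant": k, "abs_r_emf": np.abs(np.clip(r_emf, -1, 1))},
        index=table.counts.columns,
    )
    out.attrs["r_matrix"] = pd.DataFrame(r, index=table.counts.columns, columns=z.columns)
    out.attrs["p_matrix"] = pd.DataFrame(p, index=table.counts.columns, columns=z.columns)
    return out


def proportion_vs_k(
    profile: pd.DataFrame, labels: RarityLabels, max_k: int = 17
) -> pd.DataFrame:
    """Per class: proportion of its ASVs with exactly k significant functions,
    and the least-squares slope of proportion against k (k = 1..max_k)."""
    rows = []
    cls = labels.class_of()
    for c in CLASSES:
        members = profile.loc[profile.index.intersection(labels.asvs_in(c))]
        if members.empty:
            continue
        for k in range(1, max_k + 1):
            rows.append(dict(rarity_class=c, k=k,
                             proportion=float((members["k_significant"] == k).mean())))
    out = pd.DataFrame(rows)
    slopes = {}
    for c, grp in out.groupby("rarity_class"):
        fit = stats.linregress(grp["k"], grp["proportion"])
        slopes[c] = dict(slope=fit.slope, r=fit.rvalue, p=fit.pvalue)
    out.attrs["slopes"] = pd.DataFrame(slopes).T
    return out


def degree_vs_emf(
    node_topology: pd.DataFrame,
    profile: pd.DataFrame,
    labels: RarityLabels,
    min_nodes: int = 3,
) -> pd.DataFrame:
    """Per-class OLS of |r(EMF)| on node degree for network members."""
    shared = node_topology.index.intersection(profile.index)
    cls = labels.class_of()
    rows = {}
    for c in CLASSES:
        nodes = [n for n in shared if cls.get(n) == c]
        if len(nodes) < min_nodes:
            logger.warning("class %s has <%d network nodes; skipped", c, min_nodes)
            continue
        deg = node_topology.loc[nodes, "degree"].to_numpy(dtype=float)
        absr = profile.loc[nodes, "abs_r_emf"].to_numpy(dtype=float)
        ok = ~np.isnan(absr)
        if deg[ok].std() == 0 or absr[ok].std() == 0:
            rows[c] = dict(slope=0.0, r=np.nan, p=np.nan, n=int(ok.sum()))
            continue
        fit = stats.linregress(deg[ok], absr[ok])
        rows[c] = dict(slope=fit.slope, r=fit.rvalue, p=fit.pvalue, n=int(ok.sum()))
    return pd.DataFrame(rows).T


def emf_composition_mantel(
    table: AsvTable,
    emf: pd.Series,
    nperm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Mantel test of Bray-Curtis composition distance vs Euclidean EMF distance."""
    from .commstats import bray_curtis, mantel

    d_comp = bray_curtis(table)
    e = emf.loc[table.sample_ids].to_numpy()
    d_emf = pd.DataFrame(
        np.abs(e[:, None] - e[None, :]), index=table.sample_ids, columns=table.sample_ids
    )
    return mantel(d_comp, d_emf, method=method, nperm=nperm, seed=seed)
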