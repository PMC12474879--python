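"""Piecewise path models with composite variables and d-separation tests.

A path model is a DAG over observed variables; each endogenous variable is
fitted by its own OLS regression on its parents (all variables z-scored,
so coefficients are standardized effects). Goodness of fit uses Shipley's
d-separation test: for every non-adjacent variable pair the implied
conditional independence is tested by regression, and Fisher's
C = -2 sum ln p_i is compared to a chi-squared distribution with
2k degrees of freedom. Groups of predictors (e.g. per-class richness) can
be consolidated into composite variables weighted by standardized
regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import InputError

#: Default chronosequence path diagram: restoration duration drives plant
#: cover, soil pH and multifunctionality; cover and pH drive bacterial
#: richness; richness drives network degree; richness, degree, cover and
#: pH feed multifunctionality.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("duration", "cover"),
    ("duration", "pH"),
    ("duration", "EMF"),
    ("cover", "richness"),
    ("pH", "richness"),
    ("cover", "EMF"),
    ("pH", "EMF"),
    ("richness", "EMF"),
    ("richness", "degree"),
    ("degree", "EMF"),
)


@dataclass
class PathModelSpec:
    """Directed acyclic path diagram with optional composite definitions."""

    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise InputError("path model must be acyclic")
        return g

    @property
    def variables(self) -> list[str]:
        return list(nx.topological_sort(self.graph()))


@dataclass
class PathFit:
    """Standardized coefficients, per-equation R2 and Fisher's C."""

    coefficients: pd.DataFrame  # index (response, predictor): estimate, se, p
    r_squared: pd.Series
    fisher_c: float
    df: int
    p_value: float
    basis_tests: pd.DataFrame


def zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise InputError(f"zero-variance variables: {list(sd[sd == 0].index)}")
    return (df - df.mean()) / sd


def make_composite(
    data: pd.DataFrame, predictors: list[str], response: str
) -> tuple[pd.Series, pd.Series]:
    """Composite variable from standardized regression weights.

    Predictors and response are z-scored; weights are the standardized OLS
    coefficients of the response on the predictors; the composite is the
    weighted sum, re-standardized. Returns (composite scores, weights).
    """
    z = zscore(data[predictors + [response]])
    x = z[predictors].to_numpy()
    if len(predictors) > 1:
        cond = np.linalg.cond(x.T @ x)
        if cond > 1e8:
            raise InputError(f"collinear composite predictors (cond={cond:.2g})")
    beta, *_ = np.linalg.lstsq(x, z[response].to_numpy(), rcond=None)
    weights = pd.Series(beta, index=predictors, name="weight")
    comp = pd.Series(x @ beta, index=data.index)
    comp = (comp - comp.mean()) / comp.std(ddof=1)
    return comp, weights


def _basis_set(g: nx.DiGraph) -> list[tuple[str, str, tuple[str, ...]]]:
    """Shipley's independence basis set.

    One claim per unordered non-adjacent pair: the topologically later
    variable is regressed on the earlier, conditioning on the parents of
    both. Ordering is deterministic (topological sort, then name).
    """
    order = {v: i for i, v in enumerate(nx.topological_sort(g))}
    nodes = sorted(g.nodes, key=lambda v: (order[v], v))
    claims = []
    for i, x in enumerate(nodes):
        for y in nodes[i + 1:]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            cond = sorted((set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y})
            claims.append((x, y, tuple(cond)))
    return claims


def fit_path_model(spec: PathModelSpec, data: pd.DataFrame) -> PathFit:
    """Fit every structural equation by OLS and test d-separation.

    All variables are z-scored first, so each coefficient is a
    standardized effect; a single-predictor equation's coefficient equals
    the Pearson correlation. Fisher's C = -2 sum ln p over the basis-set
    claims, with df = 2 x (number of claims).
    """
    g = spec.graph()
    missing = [v for v in g.nodes if v not in data.columns]
    if missing:
        raise InputError(f"data missing variables: {missing}")
    z = zscore(data[list(g.nodes)].dropna())

    coef_rows = []
    r2 = {}
    for response in g.nodes:
        parents = sorted(g.predecessors(response))
        if not parents:
            continue
        x = sm.add_constant(z[parents])
        fit = sm.OLS(z[response], x).fit()
        r2[response] = float(fit.rsquared)
        for par in parents:
            coef_rows.append(
                dict(response=response, predictor=par,
                     estimate=float(fit.params[par]), se=float(fit.bse[par]),
                     p=float(fit.pvalues[par]))
            )
    coefficients = pd.DataFrame(coef_rows).set_index(["response", "predictor"])

    basis_rows = []
    for x_var, y_var, cond in _basis_set(g):
        preds = [x_var, *cond]
        design = sm.add_constant(z[preds])
        fit = sm.OLS(z[y_var], design).fit()
        basis_rows.append(
            dict(x=x_var, y=y_var, conditioning=",".join(cond),
                 p=float(fit.pvalues[x_var]))
        )
    basis = pd.DataFrame(basis_rows, columns=["x", "y", "conditioning", "p"])
    k = len(basis)
    if k == 0:
        c_stat, p_val = 0.0, 1.0
    else:
        c_stat = float(-2 * np.log(np.clip(basis["p"], 1e-300, 1.0)).sum())
        p_val = float(stats.chi2.sf(c_stat, df=2 * k))
    return PathFit(
        coefficients=coefficients,
        r_squared=pd.Series(r2, name="R2"),
        fisher_c=c_stat,
        df=2 * k,
        p_value=p_val,
        basis_tests=basis,
    )


def fit_with_composites(
    spec: PathModelSpec, data: pd.DataFrame
) -> tuple[PathFit, dict[str, pd.Series]]:
    """Build each declared composite, then fit the path model.

    Composite `name -> (members...)` is regressed against the first child
    of `name` in the DAG to obtain its weights (the standard
    overfitting-avoidance device for multi-indicator blocks).
    """
    g = spec.graph()
    frame = data.copy()
    weights_out = {}
    for name, members in spec.composites.items():
        children = sorted(g.successors(name))
        if not children:
            raise InputError(f"composite {name!r} has no response in the DAG")
        comp, weights = make_composite(frame, list(members), children[0])
        frame[name] = comp
        weights_out[name] = weights
    return fit_path_model(spec, frame), weights_out
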