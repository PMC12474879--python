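"""Core data containers and I/O for chronosequence community analysis.

The pipeline operates on four linked inputs: an ASV count table
(samples x ASVs), per-sample chronosequence metadata (restoration duration
in years, stage and replicate labels), a rooted phylogeny of the ASVs, and
a per-sample table of ecosystem functions. All tabular formats are UTF-8
tab-separated text; trees are newick. On disk, ASV tables follow the common
amplicon convention of ASVs as rows and samples as columns; in memory
everything is oriented samples x ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The default ecosystem-function panel: plant productivity (AGB, PC, PN, PP),
#: decomposition rate (DNA yield and six enzyme activities) and soil nutrient
#: pools (carbon, nitrogen and phosphorus fractions).
FUNCTION_NAMES: tuple[str, ...] = (
    "AGB", "PC", "PN", "PP",
    "DNA", "Suc", "b-Glu", "Cel", "Ure", "ALP", "Cat",
    "SOC", "NH4", "NO3", "STN", "SAP", "STP",
)


class InputError(ValueError):
    """Raised when an input file or table violates its contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
    if len(dup):
        raise InputError(f"duplicate {what} identifiers: {list(dup)}")


@dataclass
class AsvTable:
    """Non-negative integer ASV counts, samples x ASVs.

    Parameters
    ----------
    counts :
        DataFrame indexed by sample id with one integer column per ASV.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "ASV")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise InputError("counts must be numeric")
        if np.any(vals < 0):
            raise InputError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise InputError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[:, list(asv_ids)].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[list(sample_ids), :].copy())

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "AsvTable":
        """Read an ASV table from TSV (ASVs as rows, samples as columns)."""
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        _check_unique(df.index, "ASV")
        _check_unique(df.columns, "sample")
        num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise InputError(
                    f"non-numeric count at ASV {row!r}, sample {col!r}"
                )
            num[col] = converted
        if num.isna().any().any():
            raise InputError("missing values in count table")
        return cls(num.T)

    def to_tsv(self, path: str | Path) -> None:
        """Write the table with ASVs as rows (the on-disk convention)."""
        out = self.counts.T
        out.index.name = "asv_id"
        out.to_csv(path, sep="\t")


@dataclass
class ChronoMeta:
    """Per-sample restoration duration (years), stage label, replicate index."""

    table: pd.DataFrame  # index: sample_id; columns: duration, stage, replicate

    REQUIRED = ("duration", "stage", "replicate")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        if (self.table["duration"] < 0).any():
            raise InputError("restoration durations must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def durations(self) -> pd.Series:
        return self.table["duration"].astype(float)

    def stages(self) -> pd.Series:
        return self.table["stage"].astype(str)

    def stage_durations(self) -> pd.Series:
        """Mean duration per stage, ordered by duration."""
        return (
            self.table.groupby(self.table["stage"].astype(str))["duration"]
            .mean()
            .sort_values()
        )

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise InputError(f"metadata missing samples: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChronoMeta":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class PhyloTree:
    """Rooted phylogeny whose tips are ASV ids, with branch lengths."""

    tree: dendropy.Tree
    _pdm_cache: dict = field(default_factory=dict, repr=False)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def require_tips(self, asv_ids: Iterable[str]) -> None:
        tips = set(self.tip_labels)
        missing = [a for a in asv_ids if a not in tips]
        if missing:
            raise InputError(f"tree is missing tips for ASVs: {missing}")

    def patristic_matrix(self, asv_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Pairwise patristic (sum-of-branch-length) distances between tips.

        Cached on first call; `asv_ids` selects/orders a subset of tips.
        """
        if "full" not in self._pdm_cache:
            labels = self.tip_labels
            idx = {lab: i for i, lab in enumerate(labels)}
            n = len(labels)
            mat = np.zeros((n, n))
            # post-order merge: carry (tip indices, distances to current node)
            # up the tree; tips in different child subtrees meet at this node
            carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for node in self.tree.postorder_node_iter():
                if node.is_leaf():
                    carry[id(node)] = (
                        np.array([idx[node.taxon.label]]),
                        np.zeros(1),
                    )
                else:
                    parts = []
                    for child in node.child_nodes():
                        ids, dist = carry.pop(id(child))
                        edge = child.edge.length or 0.0
                        parts.append((ids, dist + edge))
                    for a in range(len(parts)):
                        for b in range(a + 1, len(parts)):
                            ia, da = parts[a]
                            ib, db = parts[b]
                            block = da[:, None] + db[None, :]
                            mat[np.ix_(ia, ib)] = block
                            mat[np.ix_(ib, ia)] = block.T
                    carry[id(node)] = (
                        np.concatenate([p[0] for p in parts]),
                        np.concatenate([p[1] for p in parts]),
                    )
            self._pdm_cache["full"] = pd.DataFrame(mat, index=labels, columns=labels)
        full = self._pdm_cache["full"]
        if asv_ids is None:
            return full
        self.require_tips(asv_ids)
        return full.loc[list(asv_ids), list(asv_ids)]

    @classmethod
    def from_newick(cls, path: str | Path) -> "PhyloTree":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    @classmethod
    def from_string(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def to_newick(self, path: str | Path) -> None:
        self.tree.write(path=str(path), schema="newick")


@dataclass
class FunctionTable:
    """Samples x named positive-valued ecosystem functions."""

    table: pd.DataFrame
    function_names: tuple[str, ...] = FUNCTION_NAMES

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [f for f in self.function_names if f not in self.table.columns]
        if missing:
            raise InputError(f"function table missing functions: {missing}")
        self.table = self.table.loc[:, list(self.function_names)].astype(float)
        if (self.table.to_numpy() < 0).any():
            raise InputError("function values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @classmethod
    def from_tsv(
        cls, path: str | Path, function_names: tuple[str, ...] = FUNCTION_NAMES
    ) -> "FunctionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, function_names)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# -- transforms -----------------------------------------------------------

def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Subsample every sample to `depth` reads without replacement.

    Each sample is drawn once from a multivariate hypergeometric
    distribution over its reads, so post-rarefaction counts never exceed
    the originals and every sample sums exactly to `depth`.
    """
    sums = table.sample_sums()
    low = sums[sums < depth]
    if len(low):
        raise InputError(
            f"rarefaction depth {depth} exceeds totals of samples: "
            f"{dict(low)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, (_, row) in enumerate(table.counts.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return AsvTable(pd.DataFrame(out, index=table.counts.index,
                                 columns=table.counts.columns))


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample proportions; every row sums to 1."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise InputError(f"all-zero samples: {list(zero.index)}")
    return table.counts.div(sums, axis=0)


def align_inputs(
    table: AsvTable,
    meta: ChronoMeta | None = None,
    functions: FunctionTable | None = None,
    tree: PhyloTree | None = None,
) -> tuple[AsvTable, ChronoMeta | None, FunctionTable | None]:
    """Intersect sample ids across inputs (logged); error if empty.

    The tree is only checked for tip coverage of the table's ASVs.
    """
    samples = pd.Index(table.sample_ids)
    for other in (meta, functions):
        if other is not None:
            samples = samples.intersection(other.sample_ids)
    if len(samples) == 0:
        raise InputError("no samples shared across inputs")
    if len(samples) < table.n_samples:
        logger.info(
            "sample intersection across inputs: %d of %d retained",
            len(samples), table.n_samples,
        )
    table = table.subset_samples(samples)
    if meta is not None:
        meta = ChronoMeta(meta.table.loc[samples].copy())
    if functions is not None:
        functions = FunctionTable(functions.table.loc[samples].copy(),
                                  functions.function_names)
    if tree is not None:
        tree.require_tips(table.asv_ids)
    return table, meta, functions
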