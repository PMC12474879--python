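import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from chronocomm.commstats import (
    anosim,
    bray_curtis,
    fit_richness_models,
    mantel,
    nmds,
    partition_beta,
    simper,
)
from chronocomm.io_core import AsvTable, InputError


def _table(rows, samples=None, asvs=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    asvs = asvs or [f"a{j}" for j in range(rows.shape[1])]
    return AsvTable(pd.DataFrame(rows, index=samples, columns=asvs))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        d = bray_curtis(_table([[1, 2, 0], [1, 2, 0], [0, 0, 5]]))
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 2] == 1.0

    def test_known_formula_value(self):
        d = bray_curtis(_table([[2, 1, 0], [1, 1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 20, size=(5, 8)) + 1
        d = bray_curtis(_table(x))
        expected = squareform(pdist(x, metric="braycurtis"))
        assert np.allclose(d.to_numpy(), expected, atol=1e-12)

    def test_zero_sample_rejected(self):
        with pytest.raises(InputError, match="all-zero"):
            bray_curtis(_table([[1, 1], [0, 0]]))


class TestBetaPartition:
    def test_pure_replacement(self):
        part = partition_beta(_table([[5, 0], [0, 5]]))
        row = part.pairs.iloc[0]
        assert row.balanced == pytest.approx(1.0)
        assert row.gradient == pytest.approx(0.0)

    def test_pure_nestedness(self):
        part = partition_beta(_table([[5, 5], [5, 0]]))
        row = part.pairs.iloc[0]
        assert row.balanced == pytest.approx(0.0)
        assert row.gradient == pytest.approx(row.total)

    def test_decomposition_identity_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            x = rng.integers(0, 30, size=(2, 6)) + rng.integers(0, 2, size=(2, 6))
            if (x.sum(axis=1) == 0).any():
                continue
            row = partition_beta(_table(x)).pairs.iloc[0]
            assert abs(row.balanced + row.gradient - row.total) < 1e-12

    def test_summary_shares_sum_to_one(self, toy_table):
        s = partition_beta(toy_table).summary
        assert s["similarity"] + s["balanced_share"] + s["gradient_share"] == pytest.approx(1.0)


class TestNMDS:
    def test_euclidean_configuration_has_low_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        d = pd.DataFrame(squareform(pdist(pts)), index=range(12), columns=range(12))
        coords, stress = nmds(d, seed=0)
        assert stress < 0.01

    def test_duplicate_points_nearly_coincide(self):
        pts = np.array([[0, 0], [0, 0], [3, 0], [0, 4], [2, 2]], dtype=float)
        d = pd.DataFrame(squareform(pdist(pts)), index=range(5), columns=range(5))
        coords, _ = nmds(d, seed=0)
        dup = np.linalg.norm(coords.iloc[0] - coords.iloc[1])
        span = np.linalg.norm(coords.iloc[2] - coords.iloc[3])
        assert dup < 0.05 * span

    def test_too_few_samples_rejected(self):
        d = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(InputError):
            nmds(d, k=2)


class TestAnosim:
    def _dist(self, x):
        return pd.DataFrame(squareform(pdist(x, metric="braycurtis")),
                            index=[f"s{i}" for i in range(len(x))],
                            columns=[f"s{i}" for i in range(len(x))])

    def test_perfect_separation_gives_r_one(self):
        x = np.array([[10, 0, 0], [11, 1, 0], [0, 10, 10], [0, 11, 9]], dtype=float)
        d = self._dist(x)
        groups = pd.Series(["a", "a", "b", "b"], index=d.index)
        r, _ = anosim(d, groups, nperm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_r_matches_skbio(self):
        import skbio

        rng = np.random.default_rng(6)
        x = rng.integers(1, 30, size=(6, 5)).astype(float)
        d = self._dist(x)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=d.index)
        r, _ = anosim(d, groups, nperm=99, seed=0)
        sk = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            groups.to_numpy(), permutations=0,
        )
        assert r == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_random_labels_give_uniformish_p(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 30, size=(8, 6)).astype(float)
        d = self._dist(x)
        ps = []
        for rep in range(200):
            groups = pd.Series(rng.permutation(["a"] * 4 + ["b"] * 4), index=d.index)
            _, p = anosim(d, groups, nperm=49, seed=rep)
            ps.append(p)
        assert 0.3 < np.mean(ps) < 0.7


class TestSimper:
    def test_single_asv_difference_contributes_all(self):
        t = _table([[5, 10], [5, 20]])
        groups = pd.Series(["a", "b"], index=t.sample_ids)
        res = simper(t, groups)
        assert res.loc["a1", "share"] == pytest.approx(1.0)

    def test_contributions_sum_to_pairwise_distance(self):
        t = _table([[3, 1, 4], [1, 5, 9]])
        groups = pd.Series(["a", "b"], index=t.sample_ids)
        res = simper(t, groups)
        d = bray_curtis(t).iloc[0, 1]
        assert res["contribution"].sum() == pytest.approx(d, abs=1e-12)

    def test_hand_expanded_three_asv_case(self):
        t = _table([[2, 0, 4], [1, 3, 4]])
        groups = pd.Series(["a", "b"], index=t.sample_ids)
        res = simper(t, groups)
        total = (2 + 0 + 4) + (1 + 3 + 4)
        assert res.loc["a0", "contribution"] == pytest.approx(1 / total)
        assert res.loc["a1", "contribution"] == pytest.approx(3 / total)
        assert res.loc["a2", "contribution"] == pytest.approx(0.0)


class TestMantel:
    def _toy(self, n=5, seed=8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 3))
        d = squareform(pdist(x))
        ids = [f"s{i}" for i in range(n)]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_self_correlation_is_one(self):
        d = self._toy()
        r, _ = mantel(d, d, nperm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d = self._toy()
        const = pd.DataFrame(1.0 - np.eye(5), index=d.index, columns=d.index)
        with pytest.raises(InputError, match="zero-variance"):
            mantel(d, const)

    def test_p_close_to_exhaustive_enumeration(self):
        d1 = self._toy(seed=9)
        d2 = self._toy(seed=10)
        r_obs, p_perm = mantel(d1, d2, method="pearson", nperm=999, seed=0)
        iu = np.triu_indices(5, k=1)
        v1 = d1.to_numpy()[iu]
        b = d2.to_numpy()
        count = 0
        perms = list(itertools.permutations(range(5)))
        for perm in perms:
            v2 = b[np.ix_(perm, perm)][iu]
            if stats.pearsonr(v1, v2).statistic >= r_obs - 1e-12:
                count += 1
        p_exact = count / len(perms)
        assert abs(p_perm - p_exact) < 0.05


class TestModelSelection:
    def test_exact_line_selects_linear(self):
        t = np.arange(10, dtype=float)
        res = fit_richness_models(t, 2 + 3 * t)
        assert res.index[0] == "linear"
        assert res.loc["linear", "rss"] < 1e-18

    def test_restoration_curve_recovered(self):
        t = np.repeat([0, 1, 3, 4, 5, 6, 11, 20, 23, 26, 53], 5).astype(float)
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            y = 10 * (1 - np.exp(-0.3 * t)) + rng.normal(0, 0.1, len(t))
            wins += fit_richness_models(t, y).index[0] == "restoration"
        assert wins >= 19

    def test_aic_orders_by_fit_for_equal_complexity(self):
        t = np.arange(8, dtype=float)
        y = 1 + 2 * t
        res = fit_richness_models(t, y)
        assert res.loc["linear", "aic"] < res.loc["logarithmic", "aic"]
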