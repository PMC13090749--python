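"""Distance-based tests against independent oracles.

PERMANOVA and ANOSIM statistics are cross-checked against scikit-bio, the
exact-enumeration p-values against brute-force label enumeration, and PCoA /
NMDS against synthetic Euclidean configurations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ednacongruence.community import (anosim, build_occurrence_matrix, dbrda,
                                      dispersion_test, jaccard_matrix, nmds,
                                      pcoa, permanova)


@pytest.fixture()
def euclid():
    rng = np.random.default_rng(7)
    x = rng.random((12, 5))
    return squareform(pdist(x)), np.repeat(["a", "b", "c"], 4)


class TestJaccard:
    def test_examples(self):
        occ = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 1, 0]],
                           columns=["A", "B", "C"], index=["r1", "r2", "r3"])
        d = jaccard_matrix(occ)
        assert d.loc["r1", "r2"] == pytest.approx(2 / 3)
        assert d.loc["r1", "r3"] == 0.0
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_disjoint_rows_distance_one(self):
        occ = pd.DataFrame([[1, 0], [0, 1]], columns=["A", "B"])
        assert jaccard_matrix(occ).iloc[0, 1] == 1.0

    def test_all_zero_row_rejected(self):
        occ = pd.DataFrame([[1, 0], [0, 0]], columns=["A", "B"])
        with pytest.raises(ValueError):
            jaccard_matrix(occ)


class TestPermanovaAnosim:
    def test_statistics_match_scikit_bio(self, euclid):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        from skbio.stats.distance import permanova as sk_permanova
        d, groups = euclid
        f = permanova(d, groups, n_perm=9, seed=0).statistic
        r = anosim(d, groups, n_perm=9, seed=0).statistic
        skf = sk_permanova(DistanceMatrix(d), groups, permutations=9)
        skr = sk_anosim(DistanceMatrix(d), groups, permutations=9)
        assert f == pytest.approx(skf["test statistic"], rel=1e-10)
        assert r == pytest.approx(skr["test statistic"], rel=1e-10)

    @pytest.mark.parametrize("n_per_group", [3, 4])
    def test_exact_p_matches_brute_force(self, n_per_group):
        rng = np.random.default_rng(3)
        n = 2 * n_per_group
        d = squareform(pdist(rng.random((n, 4))))
        groups = np.repeat([0, 1], n_per_group)
        mine_p = permanova(d, groups, permutations="exact").p_value
        mine_a = anosim(d, groups, permutations="exact").p_value

        d2 = d ** 2

        def pseudo_f(codes):
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(codes == g)
                sub = d2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return (sst - ssw) / (ssw / (n - 2))

        from scipy.stats import rankdata
        rank_mat = squareform(rankdata(squareform(d)))

        def anosim_r(codes):
            same = codes[:, None] == codes[None, :]
            iu = np.triu_indices(n, 1)
            rw = rank_mat[iu][same[iu]].mean()
            rb = rank_mat[iu][~same[iu]].mean()
            return (rb - rw) / (n * (n - 1) / 4)

        f_obs, r_obs = pseudo_f(groups), anosim_r(groups)
        fs, rs = [], []
        for comb in itertools.combinations(range(n), n_per_group):
            c = np.ones(n, int)
            c[list(comb)] = 0
            fs.append(pseudo_f(c))
            rs.append(anosim_r(c))
        assert mine_p == pytest.approx(np.mean(np.array(fs) >= f_obs - 1e-12))
        assert mine_a == pytest.approx(np.mean(np.array(rs) >= r_obs - 1e-12))

    def test_p_value_floor_and_range(self, euclid):
        d, groups = euclid
        res = permanova(d, groups, n_perm=99, seed=5)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_anosim_perfect_separation(self):
        # two tight clusters far apart: all between > all within
        x = np.vstack([np.random.default_rng(0).random((4, 2)),
                       np.random.default_rng(1).random((4, 2)) + 100])
        d = squareform(pdist(x))
        groups = np.repeat(["a", "b"], 4)
        assert anosim(d, groups, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_anosim_invariant_to_monotone_transform(self, euclid):
        d, groups = euclid
        r1 = anosim(d, groups, n_perm=9, seed=0).statistic
        r2 = anosim(d ** 3, groups, n_perm=9, seed=0).statistic
        assert r1 == pytest.approx(r2)

    def test_statistics_invariant_to_row_reordering(self, euclid):
        d, groups = euclid
        perm = np.random.default_rng(9).permutation(len(groups))
        f1 = permanova(d, groups, n_perm=9, seed=0).statistic
        f2 = permanova(d[np.ix_(perm, perm)], groups[perm], n_perm=9,
                       seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_single_group_rejected(self, euclid):
        d, _ = euclid
        with pytest.raises(ValueError):
            permanova(d, np.repeat("a", 12), n_perm=9, seed=0)


class TestPCoA:
    def test_euclidean_distances_reproduced(self, euclid):
        d, _ = euclid
        res = pcoa(d)
        d2 = squareform(pdist(res.coordinates))
        assert np.abs(d2 - d).max() < 1e-9

    def test_identical_rows_coincide(self):
        occ = pd.DataFrame([[1, 1, 0], [1, 1, 0], [0, 1, 1]],
                           columns=list("ABC"))
        res = pcoa(jaccard_matrix(occ).values)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_eigenvalue_sum_is_gower_trace(self, euclid):
        d, _ = euclid
        res = pcoa(d)
        n = d.shape[0]
        g = -0.5 * d ** 2
        j = np.eye(n) - 1 / n
        assert res.eigenvalues.sum() == pytest.approx(np.trace(j @ g @ j))


class TestDispersion:
    def test_equal_dispersion_mirror_groups(self):
        rng = np.random.default_rng(4)
        a = rng.random((8, 3))
        x = np.vstack([a, a + 50])  # identical internal geometry
        d = squareform(pdist(x))
        res = dispersion_test(d, np.repeat(["a", "b"], 8), n_perm=199, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_detects_scaled_dispersion(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((20, 3))
        b = 3.0 * rng.standard_normal((20, 3)) + 50
        d = squareform(pdist(np.vstack([a, b])))
        res = dispersion_test(d, np.repeat(["a", "b"], 20), n_perm=999, seed=1)
        assert res.p_value <= 0.05


class TestDbRda:
    def test_equals_classic_rda_for_euclidean_distances(self):
        rng = np.random.default_rng(5)
        x = rng.random((15, 4))
        groups = np.repeat([0, 1, 2], 5)
        d = squareform(pdist(x))
        res = dbrda(d, groups, n_perm=9, seed=0)
        # classic RDA on the centered original coordinates
        y = x - x.mean(axis=0)
        z = np.zeros((15, 3))
        z[np.arange(15), groups] = 1
        z = z - z.mean(axis=0)
        fit = z @ np.linalg.lstsq(z, y, rcond=None)[0]
        ss_fit = (fit ** 2).sum()
        ss_tot = (y ** 2).sum()
        f_oracle = (ss_fit / 2) / ((ss_tot - ss_fit) / 12)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-8)

    def test_perfect_grouping_r2_one(self):
        x = np.array([[0.0], [0.0], [10.0], [10.0]]) + \
            np.array([[0.0], [1e-9], [0.0], [1e-9]])
        d = squareform(pdist(x))
        res = dbrda(d, [0, 0, 1, 1], n_perm=9, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-6)


class TestNMDS:
    def test_embeddable_configuration_near_zero_stress(self):
        rng = np.random.default_rng(2)
        d = squareform(pdist(rng.random((10, 2))))
        res = nmds(d, k=2, seed=0, n_restarts=2)
        assert res.stress < 0.01

    def test_duplicated_observations_coincide(self):
        rng = np.random.default_rng(6)
        x = rng.random((6, 2))
        x = np.vstack([x, x[0]])
        d = squareform(pdist(x))
        res = nmds(d, k=2, seed=0, n_restarts=1)
        assert np.allclose(res.coordinates[0], res.coordinates[-1], atol=1e-8)

    def test_stress_not_above_metric_start(self):
        # the first restart starts from PCoA; iterations may only improve it
        rng = np.random.default_rng(12)
        d = squareform(pdist(rng.random((9, 3))))
        res = nmds(d, k=2, seed=0, n_restarts=1)
        from sklearn.isotonic import IsotonicRegression
        start = pcoa(d).coordinates[:, :2]
        dc = pdist(start)
        iu = np.argsort(d[np.triu_indices(9, 1)], kind="stable")
        dh = np.empty_like(dc)
        dh[iu] = IsotonicRegression(increasing=True).fit_transform(
            np.arange(dc.size, dtype=float), dc[iu])
        stress0 = np.sqrt(((dc - dh) ** 2).sum() / (dc ** 2).sum())
        assert res.stress <= stress0 + 1e-12


class TestOccurrenceMatrix:
    def test_row_counts_and_support_round_trip(self, small_collection):
        coll, _ = small_collection
        occ = build_occurrence_matrix(coll)
        with_orig = sum(1 for d in coll.datasets
                        if d.original is not None and not d.original.richness_only
                        and d.original.species)
        n_types = with_orig + 2 * len(coll)  # two reanalysis rows per dataset
        assert len(occ.data) <= n_types
        # row support equals the input species list
        ds = coll.datasets[0]
        rid = f"{ds.dataset_id}|global_reanalysis"
        support = frozenset(occ.data.columns[occ.data.loc[rid] == 1])
        assert support == ds.read_table.species
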