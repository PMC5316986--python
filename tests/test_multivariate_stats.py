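import itertools

import numpy as np
import pytest

from floraltraits import (
    TraitTable,
    bray_curtis_matrix,
    dispersion_homogeneity,
    euclidean_matrix,
    pairwise_permanova,
    permanova,
)
from floraltraits.multivariate_stats import _anova_f


def brute_force_permanova_p(d, groups):
    """Enumeration oracle: pseudo-F over all distinct label assignments."""
    d2 = d.d ** 2
    N = d.n
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    a = labels.size
    ss_t = d2.sum() / (2 * N)

    def f_of(cds):
        ssw = 0.0
        for g in range(a):
            idx = np.flatnonzero(cds == g)
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
        ssa = ss_t - ssw
        return (ssa / (a - 1)) / (ssw / (N - a))

    f_obs = f_of(codes)
    perms = sorted(set(itertools.permutations(codes.tolist())))
    hits = sum(f_of(np.array(p)) >= f_obs - 1e-12 for p in perms)
    return f_obs, hits / len(perms)


class TestDistances:
    def test_bray_curtis_hand_computed(self):
        t = TraitTable(np.array([[1.0, 0.0, 3.0], [0.0, 2.0, 2.0]]),
                       ["a", "b"], ["x", "y", "z"])
        dm = bray_curtis_matrix(t)
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_bray_curtis_extremes(self):
        t = TraitTable(np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 0.0]]),
                       ["a", "b", "c"], ["x", "y"])
        dm = bray_curtis_matrix(t)
        assert dm.d[0, 1] == pytest.approx(1.0)  # disjoint supports
        assert dm.d[0, 2] == pytest.approx(0.0)  # identical rows
        assert dm.d.max() <= 1.0 and dm.d.min() >= 0.0

    def test_bray_curtis_zero_row_rejected(self):
        t = TraitTable(np.array([[1.0, 1.0], [0.0, 0.0]]), ["a", "b"],
                       ["x", "y"])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis_matrix(t)

    def test_euclidean_345_and_rotation_invariance(self, rng):
        dm = euclidean_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dm.d[0, 1] == pytest.approx(5.0)
        pts = rng.normal(size=(6, 2))
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(
            euclidean_matrix(pts).d, euclidean_matrix(pts @ R.T).d, atol=1e-9
        )


class TestPermanova:
    def test_worked_instance(self, worked_permanova_dm):
        """0,1 | 3,4 on a line: SS_T=10, SS_W=1, SS_A=9, F=18, exact p=1/3."""
        res = permanova(worked_permanova_dm, ["A", "A", "B", "B"], exact=True)
        assert res.SS_T == pytest.approx(10.0)
        assert res.SS_W == pytest.approx(1.0)
        assert res.SS_A == pytest.approx(9.0)
        assert res.F == pytest.approx(18.0)
        assert res.p == pytest.approx(1.0 / 3.0)
        assert (res.df_between, res.df_within) == (1, 2)
        assert res.SS_A + res.SS_W == pytest.approx(res.SS_T, abs=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_classical_anova_on_one_variable(self, trial):
        """Euclidean pseudo-F on 1-D data equals the one-way ANOVA F."""
        rng = np.random.default_rng(1000 + trial)
        n_groups = rng.integers(2, 5)
        sizes = rng.integers(2, 6, size=n_groups)
        values = rng.normal(size=sizes.sum())
        groups = np.repeat([f"g{k}" for k in range(n_groups)], sizes)
        dm = euclidean_matrix(values[:, None])
        res = permanova(dm, groups, n_perm=9, seed=0)
        _, codes = np.unique(groups, return_inverse=True)
        f_classical = _anova_f(values, codes, n_groups)
        assert res.F == pytest.approx(f_classical, abs=1e-9)

    def test_sampled_p_converges_to_exact(self, rng):
        values = rng.normal(size=8)
        groups = ["A"] * 4 + ["B"] * 4
        dm = euclidean_matrix(values[:, None])
        f_obs, p_exact = brute_force_permanova_p(dm, groups)
        res_exact = permanova(dm, groups, exact=True)
        assert res_exact.p == pytest.approx(p_exact, abs=1e-12)
        res = permanova(dm, groups, n_perm=3999, seed=5)
        # add-one sampled estimate vs exact enumeration: MC tolerance
        assert res.p == pytest.approx(p_exact, abs=0.035)

    def test_invariant_to_reordering_and_renaming(self, rng):
        values = rng.normal(size=(9, 3))
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        dm = euclidean_matrix(values)
        res1 = permanova(dm, groups, n_perm=99, seed=2)
        perm = rng.permutation(9)
        dm2 = euclidean_matrix(values[perm])
        res2 = permanova(dm2, groups[perm], n_perm=99, seed=2)
        assert res1.F == pytest.approx(res2.F, abs=1e-9)
        renames = {"a": "zebra", "b": "yak", "c": "xerus"}
        res3 = permanova(dm, [renames[g] for g in groups], n_perm=99, seed=2)
        assert res1.F == pytest.approx(res3.F, abs=1e-12)
        assert res1.p == pytest.approx(res3.p, abs=1e-12)

    def test_identical_samples_degenerate(self):
        dm = euclidean_matrix(np.zeros((5, 2)))
        res = permanova(dm, ["A", "A", "B", "B", "B"], n_perm=99, seed=0)
        assert res.F == 0.0 and res.p == 1.0 and res.SS_T == 0.0

    def test_determinism_same_seed(self, rng):
        values = rng.normal(size=(10, 4))
        dm = euclidean_matrix(values)
        groups = ["A"] * 5 + ["B"] * 5
        r1 = permanova(dm, groups, n_perm=199, seed=42)
        r2 = permanova(dm, groups, n_perm=199, seed=42)
        assert r1.p == r2.p and r1.F == r2.F


class TestPairwisePermanova:
    def test_two_groups_factor_one(self, rng):
        values = rng.normal(size=(8, 2))
        dm = euclidean_matrix(values)
        rows = pairwise_permanova(dm, ["A"] * 4 + ["B"] * 4, n_perm=99, seed=1)
        assert len(rows) == 1
        assert rows[0].p_adjusted == pytest.approx(rows[0].p_raw)

    def test_three_groups_bonferroni_capped(self, rng):
        values = rng.normal(size=(9, 2))
        dm = euclidean_matrix(values)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        rows = pairwise_permanova(dm, groups, n_perm=99, seed=1)
        assert len(rows) == 3
        for r in rows:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))

    def test_submatrix_equals_direct_run(self, rng):
        """Pair (A,B) sub-test equals permanova on only those samples."""
        values = rng.normal(size=(9, 2))
        values[6:] += 4.0
        dm = euclidean_matrix(values)
        groups = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        rows = pairwise_permanova(dm, groups, n_perm=199, seed=7)
        ab = next(r for r in rows if r.pair == ("A", "B"))
        sub = euclidean_matrix(values[:6])
        direct = permanova(sub, groups[:6], n_perm=199, seed=7)
        assert ab.F == pytest.approx(direct.F, abs=1e-12)
        assert ab.p_raw == pytest.approx(direct.p, abs=1e-12)


class TestDispersion:
    def test_hand_computed_1d(self):
        """Groups {0,1,2} and {10,14,18}: z=(1,0,1|4,0,4), F=72/34."""
        dm = euclidean_matrix(np.array([[0.0], [1.0], [2.0],
                                        [10.0], [14.0], [18.0]]))
        res = dispersion_homogeneity(dm, ["A"] * 3 + ["B"] * 3,
                                     n_perm=99, seed=0)
        np.testing.assert_allclose(sorted(res.z[:3]), [0, 1, 1], atol=1e-9)
        np.testing.assert_allclose(sorted(res.z[3:]), [0, 4, 4], atol=1e-9)
        assert res.F == pytest.approx(72.0 / 34.0, abs=1e-9)

    def test_mirror_groups_identical_dispersion(self, rng):
        pts = rng.normal(size=(5, 2))
        values = np.vstack([pts, -pts + 10.0])  # mirror image, shifted
        dm = euclidean_matrix(values)
        res = dispersion_homogeneity(dm, ["A"] * 5 + ["B"] * 5,
                                     n_perm=199, seed=3)
        z_a = np.sort(res.z[:5])
        z_b = np.sort(res.z[5:])
        np.testing.assert_allclose(z_a, z_b, atol=1e-9)
        assert res.F == pytest.approx(0.0, abs=1e-18)

    def test_identical_points_zero_dispersion(self):
        values = np.vstack([np.zeros((3, 2)), np.array([[1.0, 0], [3, 0], [5, 0]])])
        dm = euclidean_matrix(values)
        res = dispersion_homogeneity(dm, ["A"] * 3 + ["B"] * 3,
                                     n_perm=99, seed=1)
        np.testing.assert_allclose(res.z[:3], 0.0, atol=1e-9)

    def test_bray_curtis_negative_axes_handled(self, rng):
        """Non-Euclidean dissimilarity: embedding still yields real z >= 0."""
        vals = rng.gamma(1.0, size=(12, 6))
        t = TraitTable(vals, [f"s{i}" for i in range(12)],
                       [f"v{j}" for j in range(6)])
        dm = bray_curtis_matrix(t)
        res = dispersion_homogeneity(dm, ["A"] * 6 + ["B"] * 6,
                                     n_perm=99, seed=2)
        assert np.isfinite(res.z).all() and (res.z >= 0).all()
        assert np.isfinite(res.F)


class TestPermanovaAgainstSkbio:
    def test_cross_check_against_independent_implementation(self, rng):
        """pseudo-F and permutation machinery agree with scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        values = rng.normal(size=(12, 4))
        values[6:] += 1.0
        dm = euclidean_matrix(values, [f"s{i}" for i in range(12)])
        groups = ["A"] * 6 + ["B"] * 6
        res = permanova(dm, groups, n_perm=999, seed=11)
        sk_dm = skbio_stats.DistanceMatrix(dm.d, dm.labels)
        sk = skbio_stats.permanova(sk_dm, grouping=groups, permutations=999)
        assert res.F == pytest.approx(float(sk["test statistic"]), abs=1e-9)
        assert res.p == pytest.approx(float(sk["p-value"]), abs=0.05)
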