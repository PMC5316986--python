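import numpy as np
import pytest
from scipy.stats import norm

from floraltraits import (
    DistanceMatrix,
    TraitTable,
    fit_au,
    multiscale_bootstrap,
    upgma,
    write_newick,
)
from floraltraits.hier_clustering import DEFAULT_SCALES

from conftest import random_distance_matrix


def brute_force_upgma(d: DistanceMatrix):
    """Independent oracle: recompute every pair average from leaf members
    at each step instead of updating the matrix incrementally."""
    clusters = {i: [i] for i in range(d.n)}
    labels = {i: min(d.labels[j] for j in [i]) for i in range(d.n)}
    merges = []
    next_id = d.n
    D0 = d.d

    def avg(a, b):
        return np.mean([D0[i, j] for i in clusters[a] for j in clusters[b]])

    while len(clusters) > 1:
        best = None
        for a in list(clusters):
            for b in list(clusters):
                if a >= b:
                    continue
                key = tuple(sorted((labels[a], labels[b])))
                cand = (avg(a, b), key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, a, b = best
        merges.append((frozenset(d.labels[i] for i in clusters[a] + clusters[b]),
                       dist / 2.0))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        labels[next_id] = min(labels.get(a, "~"), labels.get(b, "~"),
                              *(d.labels[i] for i in clusters[next_id]))
        next_id += 1
    return merges


class TestUpgma:
    def test_worked_three_leaf_example(self, three_leaf_dm):
        tree = upgma(three_leaf_dm)
        assert [h for _, _, h in tree.merges] == pytest.approx([1.0, 3.0])
        assert write_newick(tree) == "((A:1,B:1):2,C:3);"

    def test_two_leaves(self):
        dm = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ["x", "y"])
        tree = upgma(dm)
        assert tree.merges[0][2] == pytest.approx(1.5)

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_matches_brute_force_oracle(self, n):
        for trial in range(20):
            rng = np.random.default_rng(7000 + 100 * n + trial)
            dm = random_distance_matrix(rng, n)
            tree = upgma(dm)
            got = list(zip(tree.node_clades(), [h for _, _, h in tree.merges]))
            expected = brute_force_upgma(dm)
            assert len(got) == len(expected)
            for (cl_g, h_g), (cl_e, h_e) in zip(got, expected):
                assert cl_g == cl_e
                assert h_g == pytest.approx(h_e, abs=1e-9)

    def test_ultrametric_on_random_instances(self, rng):
        for _ in range(10):
            dm = random_distance_matrix(rng, 9)
            tree = upgma(dm)
            coph = tree.cophenetic().d
            # three-point ultrametric condition
            n = dm.n
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert coph[i, j] <= max(coph[i, k], coph[k, j]) + 1e-9
            # heights non-decreasing along every root path: merge heights
            # of nested clades are ordered automatically if sorted output
            heights = [h for _, _, h in tree.merges]
            clades = tree.node_clades()
            for a in range(len(clades)):
                for b in range(len(clades)):
                    if clades[a] < clades[b]:
                        assert heights[a] <= heights[b] + 1e-9

    def test_input_order_invariance(self, rng):
        dm = random_distance_matrix(rng, 7)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix(dm.d[np.ix_(perm, perm)],
                             [dm.labels[i] for i in perm])
        t1, t2 = upgma(dm), upgma(dm2)
        assert t1.node_clades() == t2.node_clades()

    def test_tie_break_lexicographic(self):
        # equidistant triangle: must merge the lexicographically first pair
        d = np.full((3, 3), 4.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ["zeta", "alpha", "mid"])
        tree = upgma(dm)
        assert tree.node_clades()[0] == frozenset({"alpha", "mid"})


class TestFitAu:
    def test_flat_half_curve_gives_au_half(self):
        bp = np.full(10, 0.5)
        v, c, au, bp1 = fit_au(bp, DEFAULT_SCALES, 1000)
        assert v == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert au == pytest.approx(0.5, abs=1e-12)

    def test_recovers_noiseless_model(self):
        """BP curves generated from (v=1, c=0.5) invert exactly."""
        sigma = np.array([0.5, 1.0, 2.0])
        scales = 1.0 / sigma ** 2
        bp = 1.0 - norm.cdf(1.0 * sigma + 0.5 / sigma)
        v, c, au, _ = fit_au(bp, scales, 1000)
        assert v == pytest.approx(1.0, abs=1e-6)
        assert c == pytest.approx(0.5, abs=1e-6)
        assert au == pytest.approx(1.0 - norm.cdf(0.5), abs=1e-6)

    def test_no_curvature_means_au_equals_bp_at_sigma_one(self):
        sigma = 1.0 / np.sqrt(np.asarray(DEFAULT_SCALES))
        v_true = 0.7
        bp = 1.0 - norm.cdf(v_true * sigma)
        v, c, au, _ = fit_au(bp, DEFAULT_SCALES, 1000)
        assert c == pytest.approx(0.0, abs=1e-9)
        assert au == pytest.approx(1.0 - norm.cdf(v_true), abs=1e-9)

    def test_saturated_curves_capped(self):
        v, c, au, bp1 = fit_au(np.ones(5), np.linspace(0.5, 1.4, 5), 100)
        assert au == 1.0 and bp1 == 1.0
        v, c, au, bp1 = fit_au(np.zeros(5), np.linspace(0.5, 1.4, 5), 100)
        assert au == 0.0 and bp1 == 0.0


@pytest.fixture(scope="module")
def clustered_table():
    rng = np.random.default_rng(99)
    centers = np.array([[0.0] * 10 + [5.0] * 10 + [0.0] * 10,
                        [5.0] * 10 + [0.0] * 10 + [0.0] * 10,
                        [0.0] * 10 + [0.0] * 10 + [5.0] * 10])
    rows, ids = [], []
    for ci, c in enumerate(centers):
        for r in range(3):
            rows.append(np.abs(c + rng.normal(0, 0.3, size=30)))
            ids.append(f"c{ci}_s{r}")
    return TraitTable(np.vstack(rows), ids, [f"v{j}" for j in range(30)])


class TestMultiscaleBootstrap:
    def test_determinism_and_identical_pairs(self, clustered_table):
        t1 = multiscale_bootstrap(clustered_table, metric="euclidean",
                                  scales=(0.6, 1.0, 1.4), n_boot=50, seed=4)
        t2 = multiscale_bootstrap(clustered_table, metric="euclidean",
                                  scales=(0.6, 1.0, 1.4), n_boot=50, seed=4)
        for s1, s2 in zip(t1[1], t2[1]):
            np.testing.assert_array_equal(s1.bp_per_scale, s2.bp_per_scale)

    def test_duplicate_samples_form_certain_clade(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 5, size=(4, 12))
        vals[1] = vals[0]  # two identical samples
        t = TraitTable(vals, ["dupA", "dupB", "s3", "s4"],
                       [f"v{j}" for j in range(12)])
        tree, supports = multiscale_bootstrap(
            t, metric="bray_curtis", scales=(0.5, 1.0, 1.4), n_boot=60, seed=0
        )
        pair = next(s for s in supports
                    if s.clade == frozenset({"dupA", "dupB"}))
        np.testing.assert_allclose(pair.bp_per_scale, 1.0)
        assert pair.AU == 1.0

    def test_strong_clusters_reach_high_au(self, clustered_table):
        tree, supports = multiscale_bootstrap(
            clustered_table, metric="euclidean",
            scales=(0.6, 0.8, 1.0, 1.2, 1.4), n_boot=200, seed=1
        )
        by_clade = {s.clade: s for s in supports}
        for ci in range(3):
            clade = frozenset(f"c{ci}_s{r}" for r in range(3))
            assert clade in by_clade
            assert by_clade[clade].AU > 0.9

    def test_scale_too_small_rejected(self, clustered_table):
        with pytest.raises(ValueError, match="fewer than 2"):
            multiscale_bootstrap(clustered_table, metric="euclidean",
                                 scales=(0.01,), n_boot=5, seed=0)


class TestNewick:
    def test_round_trip_topology_and_heights(self, rng):
        dendropy = pytest.importorskip("dendropy")
        dm = random_distance_matrix(rng, 6)
        tree = upgma(dm)
        nwk = write_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {lf.taxon.label for lf in parsed.leaf_node_iter()}
        assert taxa == set(tree.leaves)
        pdm = parsed.phylogenetic_distance_matrix()
        coph = tree.cophenetic()
        for i, a in enumerate(tree.leaves):
            for j, b in enumerate(tree.leaves):
                if i < j:
                    ta = parsed.taxon_namespace.get_taxon(a)
                    tb = parsed.taxon_namespace.get_taxon(b)
                    assert pdm.patristic_distance(ta, tb) == pytest.approx(
                        coph.d[i, j], abs=1e-6
                    )

    def test_labels_with_commas_quoted(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        dm = DistanceMatrix(d, ["a,1", "b"])
        nwk = write_newick(upgma(dm))
        assert "'a,1'" in nwk

    def test_support_annotations_emitted(self, clustered_tree_with_supports):
        tree, supports = clustered_tree_with_supports
        nwk = write_newick(tree, supports)
        assert "[&AU=" in nwk and "BP=" in nwk


@pytest.fixture(scope="module")
def clustered_tree_with_supports():
    rng = np.random.default_rng(12)
    vals = rng.uniform(0.5, 3.0, size=(5, 15))
    vals[:2] *= 4.0
    t = TraitTable(vals, [f"s{i}" for i in range(5)],
                   [f"v{j}" for j in range(15)])
    return multiscale_bootstrap(t, metric="euclidean",
                                scales=(0.7, 1.0, 1.3), n_boot=40, seed=8)
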