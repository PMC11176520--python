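import numpy as np
import pytest
from scipy.spatial import procrustes

import divkit as dk
from divkit.structure import (
    DistanceMatrix,
    classical_mds,
    fst_matrix,
    ibs_distance,
    neighbor_joining,
    pairwise_fst,
    reynolds_distance,
    to_newick,
    wc_theta,
)
from conftest import random_dataset


def dataset_with(calls, groups=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return dk.GenotypeDataset(
        dk.make_sample_table(
            ["f"] * n, [f"i{k}" for k in range(n)], groups=groups
        ),
        dk.make_marker_table([f"m{i}" for i in range(m)], ["1"] * m, np.arange(1, m + 1) * 1000),
        calls,
    )


class TestIBS:
    def test_identical_individuals_distance_zero(self):
        rng = np.random.default_rng(90)
        row = rng.integers(0, 3, 50).astype(np.int8)
        d = ibs_distance(dataset_with(np.vstack([row, row])))
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = ibs_distance(dataset_with([[0] * 20, [2] * 20]))
        assert d.values[0, 1] == 1.0

    def test_hand_fixture_one_sixth(self):
        # dosages (0,1), (2,2), (1,1): |diff| = 1, 0, 0 -> 1 / (2*3)
        d = ibs_distance(dataset_with([[0, 2, 1], [1, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(1 / 6)

    def test_metric_triangle_inequality(self):
        rng = np.random.default_rng(91)
        ds = random_dataset(rng, 8, 100)
        d = ibs_distance(ds).values
        for a in range(8):
            for b in range(8):
                for c in range(8):
                    assert d[a, b] <= d[a, c] + d[c, b] + 1e-12

    def test_missing_pair_policy(self):
        calls = np.array([[0, dk.MISSING], [dk.MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="allow_missing_pairs"):
            ibs_distance(dataset_with(calls))
        d = ibs_distance(dataset_with(calls), allow_missing_pairs=True)
        assert np.isnan(d.values[0, 1])


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], m)

    def test_nonzero_diagonal_rejected(self):
        m = np.array([[1.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], m)

    def test_phylip_round_shape(self):
        m = np.array([[0.0, 0.25], [0.25, 0.0]])
        text = DistanceMatrix(["a", "b"], m).to_phylip()
        lines = text.strip().split("\n")
        assert lines[0] == "2" and len(lines) == 3


class TestMDS:
    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(92)
        X = rng.normal(size=(12, 2))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([f"s{i}" for i in range(12)], D), k=2)
        _, _, disparity = procrustes(X, res.coordinates)
        assert disparity < 1e-12
        # a genuinely 2-D configuration is fully explained in 2 axes
        assert res.explained.sum() == pytest.approx(1.0)

    def test_collinear_points_one_positive_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = classical_mds(DistanceMatrix(list("abcd"), D), k=2)
        assert res.coordinates.shape[1] == 1

    def test_explained_fractions_descending(self):
        rng = np.random.default_rng(93)
        ds = random_dataset(rng, 15, 200)
        res = classical_mds(ibs_distance(ds), k=2)
        assert res.explained[0] >= res.explained[1] > 0


class TestWCTheta:
    def test_textbook_two_locus_hand_computation(self):
        # pop A: genotypes 0,0,2,2 ; pop B: 2,2,2,2 at locus 1
        # locus 2 identical in both pops (no signal)
        calls = np.array(
            [[0, 1], [0, 1], [2, 1], [2, 1], [2, 1], [2, 1], [2, 1], [2, 1]],
            dtype=np.int8,
        )
        ds = dataset_with(calls)
        theta = wc_theta(ds, np.arange(4), np.arange(4, 8))
        # independent recount with the canonical per-locus formulas
        def components(p1, p2, h1, h2, n1, n2):
            r, nbar = 2.0, (n1 + n2) / 2
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            return a, b, c
        a1, b1, c1 = components(0.5, 1.0, 0.0, 0.0, 4, 4)
        a2, b2, c2 = components(0.5, 0.5, 1.0, 1.0, 4, 4)
        expect = (a1 + a2) / (a1 + b1 + c1 + a2 + b2 + c2)
        assert theta == pytest.approx(expect)

    def test_fixed_differences_give_theta_one(self):
        calls = np.vstack([np.zeros((30, 40)), np.full((30, 40), 2)]).astype(np.int8)
        theta = wc_theta(dataset_with(calls), np.arange(30), np.arange(30, 60))
        assert theta == pytest.approx(1.0)

    def test_population_swap_symmetric(self):
        rng = np.random.default_rng(94)
        ds = random_dataset(rng, 20, 100)
        a, b = np.arange(10), np.arange(10, 20)
        assert wc_theta(ds, a, b) == pytest.approx(wc_theta(ds, b, a))

    def test_recovers_parametric_fst(self):
        ds, _ = dk.sim_structured(
            dk.StructuredSimConfig(n_pops=2, n_per_pop=50, n_loci=5000, fst_per_pop=0.05, seed=95)
        )
        theta = wc_theta(ds, np.arange(50), np.arange(50, 100))
        assert theta == pytest.approx(0.05, abs=0.01)

    def test_null_panel_theta_near_zero(self):
        rng = np.random.default_rng(96)
        calls = rng.binomial(2, rng.uniform(0.2, 0.8, 3000), size=(60, 3000)).astype(np.int8)
        theta = wc_theta(dataset_with(calls), np.arange(30), np.arange(30, 60))
        assert abs(theta) < 0.005

    def test_small_population_rejected(self):
        rng = np.random.default_rng(97)
        ds = random_dataset(rng, 5, 20)
        with pytest.raises(ValueError, match="at least 2"):
            wc_theta(ds, np.array([0]), np.arange(1, 5))


class TestReynolds:
    def test_known_value(self):
        assert reynolds_distance(0.1) == pytest.approx(0.1053605, abs=1e-6)

    def test_negative_theta_clamped(self):
        assert reynolds_distance(-0.02) == 0.0

    def test_theta_one_infinite(self):
        assert reynolds_distance(1.0) == float("inf")

    def test_monotone(self):
        thetas = [0.0, 0.05, 0.1, 0.5, 0.9]
        ds = [reynolds_distance(t) for t in thetas]
        assert ds == sorted(ds)


class TestPairwise:
    def test_all_pairs_present(self):
        ds, _ = dk.sim_structured(
            dk.StructuredSimConfig(n_pops=3, n_per_pop=15, n_loci=500, seed=98)
        )
        stats = pairwise_fst(ds)
        assert {(s.pop_a, s.pop_b) for s in stats} == {
            ("pop1", "pop2"), ("pop1", "pop3"), ("pop2", "pop3")
        }
        m = fst_matrix(stats, "theta")
        assert m.labels == ["pop1", "pop2", "pop3"]
        assert m.values[0, 1] == pytest.approx(max(stats[0].theta, 0.0))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(ab)=3, d(ac)=4, d(bc)=5 -> leaf branches 1, 2, 3
        D = DistanceMatrix(list("abc"), np.array(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float
        ))
        tree = neighbor_joining(D)
        # closed form: leaf branches 1, 2, 3 from one internal node, so
        # every tip-to-tip path length reproduces the input exactly
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(3)
        assert tree.find("a").distance(tree.find("c")) == pytest.approx(4)
        assert tree.find("b").distance(tree.find("c")) == pytest.approx(5)

    def test_additive_five_taxon_distances_reproduced(self):
        # random tree-generated additive matrix: NJ must reproduce all
        # pairwise path lengths exactly
        rng = np.random.default_rng(99)
        # caterpillar tree ((a,b),(c,(d,e))) with random branch lengths
        bl = rng.uniform(0.5, 2.0, size=8)
        a, b, c, d, e, x, y, z = bl  # leaves a..e, internals x (ab), y (de), z joins
        labels = list("abcde")
        path = {
            ("a", "b"): a + b,
            ("a", "c"): a + x + c,
            ("a", "d"): a + x + z + d + y,
            ("a", "e"): a + x + z + e + y,
            ("b", "c"): b + x + c,
            ("b", "d"): b + x + z + d + y,
            ("b", "e"): b + x + z + e + y,
            ("c", "d"): c + z + d + y,
            ("c", "e"): c + z + e + y,
            ("d", "e"): d + e,
        }
        m = np.zeros((5, 5))
        for (u, v), w in path.items():
            i, j = labels.index(u), labels.index(v)
            m[i, j] = m[j, i] = w
        tree = neighbor_joining(DistanceMatrix(labels, m))
        for (u, v), w in path.items():
            assert tree.find(u).distance(tree.find(v)) == pytest.approx(w)

    def test_label_permutation_invariant_topology(self):
        rng = np.random.default_rng(100)
        n = 6
        X = rng.normal(size=(n, 4))
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = rng.permutation(n)
        t2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)])
        )
        assert t1.compare_rfd(t2) == 0

    def test_two_taxa_trivial_tree(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        with pytest.warns(UserWarning, match="trivial"):
            tree = neighbor_joining(D)
        assert sorted(t.name for t in tree.tips()) == ["a", "b"]

    def test_newick_serialization_contains_all_taxa(self):
        rng = np.random.default_rng(101)
        ds = random_dataset(rng, 6, 80)
        tree = neighbor_joining(ibs_distance(ds))
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        for lab in ds.sample_ids():
            assert lab in nwk
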