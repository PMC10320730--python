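import numpy as np
import pytest

from saelgmda.io_formats import AssociationMatrix
from saelgmda.similarity import (
    GipkConfig,
    disease_functional_similarity,
    fuse_similarity,
    gene_to_set_score,
    gipk_similarity,
    normalize_lls,
)

from helpers import make_network


class TestNormalizeLls:
    def test_minmax_endpoints(self):
        net = make_network([("a", "b", 1.0), ("b", "c", 3.0), ("c", "d", 5.0)])
        out = normalize_lls(net)
        assert out.score("a", "b") == 0.0
        assert out.score("b", "c") == 0.5
        assert out.score("c", "d") == 1.0

    def test_degenerate_range_is_an_error(self):
        net = make_network([("a", "b", 2.0), ("c", "d", 2.0)])
        with pytest.raises(ValueError, match="degenerate score range"):
            normalize_lls(net)

    def test_order_preserved_and_range_exact(self, rng):
        scores = rng.normal(size=50)
        net = make_network(
            [(f"g{i}", f"h{i}", s) for i, s in enumerate(scores)]
        )
        out = normalize_lls(net)
        normed = np.array([out.score(f"g{i}", f"h{i}") for i in range(50)])
        assert normed.min() == 0.0 and normed.max() == 1.0
        assert np.array_equal(np.argsort(normed), np.argsort(scores))


class TestGeneToSetScore:
    def test_shared_gene_dominates(self):
        net = make_network([("g1", "g2", 0.3)])
        assert gene_to_set_score("g1", {"g1", "g2"}, net) == 1.0

    def test_absent_pairs_score_zero(self):
        net = make_network([("x", "y", 0.5)])
        assert gene_to_set_score("g1", {"g2"}, net) == 0.0

    def test_best_match_is_the_maximum(self):
        net = make_network([("g", "a", 0.3), ("g", "b", 0.8)])
        assert gene_to_set_score("g", {"a", "b"}, net) == 0.8

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            gene_to_set_score("g", set(), make_network([("a", "b", 1.0)]))


class TestDiseaseFunctionalSimilarity:
    def test_identical_gene_sets_score_one(self):
        dg = {"d1": {"g1", "g2"}, "d2": {"g1", "g2"}}
        D = disease_functional_similarity(dg, make_network([]), ["d1", "d2"])
        assert D[0, 1] == 1.0 and D[0, 0] == 1.0

    def test_unlinked_singletons_score_zero(self):
        dg = {"d1": {"g1"}, "d2": {"g2"}}
        D = disease_functional_similarity(dg, make_network([]), ["d1", "d2"])
        assert D[0, 1] == 0.0

    def test_hand_computed_two_way_best_match(self):
        # G_i={g1}, G_j={g2,g3}: best matches 0.9 | 0.4, 0.9 -> 2.2/3
        net = make_network([("g1", "g2", 0.4), ("g1", "g3", 0.9)])
        dg = {"di": {"g1"}, "dj": {"g2", "g3"}}
        D = disease_functional_similarity(dg, net, ["di", "dj"])
        assert D[0, 1] == pytest.approx((0.9 + 0.4 + 0.9) / 3, abs=1e-12)

    def test_empty_gene_set_gives_zero_row(self):
        dg = {"d1": {"g1"}}
        D = disease_functional_similarity(dg, make_network([]), ["d1", "d2"])
        assert D[1, :].tolist() == [0.0, 0.0]
        assert D[0, 0] == 1.0

    def test_matches_brute_force_double_sum_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        edges = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < 0.4:
                    edges.append((genes[i], genes[j], float(rng.random())))
        net = make_network(edges)
        diseases = [f"d{i}" for i in range(5)]
        dg = {
            d: set(rng.choice(genes, size=rng.integers(1, 6), replace=False))
            for d in diseases
        }
        D = disease_functional_similarity(dg, net, diseases)

        def fs(a, b):
            return 1.0 if a == b else net.score(a, b, default=0.0)

        for i, di in enumerate(diseases):
            for j, dj in enumerate(diseases):
                gi, gj = dg[di], dg[dj]
                expected = (
                    sum(max(fs(g, t) for t in gj) for g in gi)
                    + sum(max(fs(g, t) for t in gi) for g in gj)
                ) / (len(gi) + len(gj))
                assert D[i, j] == pytest.approx(expected, abs=1e-12)


class TestGipkSimilarity:
    def test_identical_profiles_score_one(self):
        values = np.array([[1, 0, 1], [1, 0, 1]], dtype=np.int8)
        X = AssociationMatrix(values, ("d1", "d2"), ("m1", "m2", "m3"))
        S = gipk_similarity(X, "disease")
        assert S[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_2x2_identity_hand_value(self):
        X = AssociationMatrix(np.eye(2, dtype=np.int8), ("d1", "d2"), ("m1", "m2"))
        S = gipk_similarity(X, "disease")
        # mean squared profile norm 1 -> gamma 1; ||(1,0)-(0,1)||^2 = 2
        assert S[0, 1] == pytest.approx(np.exp(-2), abs=1e-12)

    def test_kernel_properties(self, random_assoc):
        for axis in ("disease", "microbe"):
            S = gipk_similarity(random_assoc, axis)
            assert np.abs(S - S.T).max() <= 1e-9
            assert np.all(np.diag(S) == 1.0)
            assert S.min() > 0 and S.max() <= 1.0

    def test_matches_two_loop_brute_force(self, random_assoc):
        S = gipk_similarity(random_assoc, "disease")
        profiles = random_assoc.values.astype(float)
        gamma = 1.0 / np.mean([p @ p for p in profiles])
        for i in range(len(profiles)):
            for j in range(len(profiles)):
                if i == j:
                    continue
                d = profiles[i] - profiles[j]
                assert S[i, j] == pytest.approx(np.exp(-gamma * (d @ d)), abs=1e-12)

    def test_bandwidth_monotonicity(self, random_assoc):
        S1 = gipk_similarity(random_assoc, "microbe", GipkConfig(1.0))
        S2 = gipk_similarity(random_assoc, "microbe", GipkConfig(2.0))
        off = ~np.eye(S1.shape[0], dtype=bool)
        distinct = off & (S1 < 1.0)
        assert np.all(S2[distinct] < S1[distinct])

    def test_all_zero_matrix_is_an_error(self):
        X = AssociationMatrix(np.zeros((2, 2), dtype=np.int8), ("d1", "d2"), ("m1", "m2"))
        with pytest.raises(ValueError, match="empty interaction profiles"):
            gipk_similarity(X, "disease")


class TestFuseSimilarity:
    def test_average_where_functional_nonzero(self):
        F = np.array([[1.0, 0.6], [0.6, 1.0]])
        G = np.array([[1.0, 0.4], [0.4, 1.0]])
        for mode in ("gipk_fallback", "paper_literal"):
            assert fuse_similarity(F, G, mode)[0, 1] == pytest.approx(0.5)

    def test_zero_branch_semantics(self):
        F = np.zeros((2, 2))
        G = np.full((2, 2), 0.4)
        assert fuse_similarity(F, G, "gipk_fallback")[0, 1] == 0.4
        assert fuse_similarity(F, G, "paper_literal")[0, 1] == 0.0

    def test_all_zero_functional_falls_back_to_kernel(self, rng):
        G = rng.random((4, 4))
        out = fuse_similarity(np.zeros((4, 4)), G, "gipk_fallback")
        assert np.array_equal(out, G)

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            fuse_similarity(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_outputs_symmetric_and_bounded(self, random_assoc):
        G = gipk_similarity(random_assoc, "disease")
        F = np.clip(G - 0.2, 0, 1)
        out = fuse_similarity(F, G)
        assert np.abs(out - out.T).max() <= 1e-9
        assert out.min() >= 0 and out.max() <= 1.0
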