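"""Unit and property tests for the pairwise similarity measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrepo.containers import BipartiteNetwork, DrugVocabulary
from drugrepo.errors import MissingDataError
from drugrepo.similarity import (
    atc_similarity,
    build_similarity_network,
    jaccard,
    jaccard_network,
    set_tanimoto,
    sw_similarity,
    tanimoto,
    target_similarity,
)

from _oracles import sw_similarity_dp


def fp(*bits):
    return np.array(bits, dtype=int)


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        f = fp(1, 0, 1, 1, 0)
        assert tanimoto(f, f) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(fp(1, 1, 0, 0), fp(0, 0, 1, 1)) == 0.0

    def test_printed_formula_case(self):
        # a=10, b=8, c=4 -> 4/14
        a = np.r_[np.ones(4), np.ones(6), np.zeros(4), np.zeros(4)].astype(int)
        b = np.r_[np.ones(4), np.zeros(6), np.ones(4), np.zeros(4)].astype(int)
        assert tanimoto(a, b) == pytest.approx(4 / 14)

    def test_both_empty_is_zero(self):
        z = np.zeros(8, dtype=int)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(fp(1, 0), fp(1, 0, 1))

    @given(st.lists(st.booleans(), min_size=1, max_size=40),
           st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_equals_jaccard_on_supports(self, xs, ys):
        n = max(len(xs), len(ys))
        a = np.array(xs + [False] * (n - len(xs)), dtype=int)
        b = np.array(ys + [False] * (n - len(ys)), dtype=int)
        sa = {i for i, v in enumerate(a) if v}
        sb = {i for i, v in enumerate(b) if v}
        assert tanimoto(a, b) == pytest.approx(jaccard(sa, sb))


class TestSetMeasures:
    def test_set_tanimoto_examples(self):
        assert set_tanimoto({"a", "b"}, {"a", "b"}) == 1.0
        assert set_tanimoto({"s1", "s2", "s3"}, {"s3", "s4"}) == pytest.approx(0.25)
        assert set_tanimoto(set(), set()) == 0.0

    def test_jaccard_examples(self):
        assert jaccard({"x"}, {"x"}) == 1.0
        assert jaccard({"x"}, {"y"}) == 0.0
        assert jaccard({1, 2, 3}, {2, 3, 4, 5}) == pytest.approx(0.4)
        assert jaccard(set(), set()) == 0.0

    @given(st.sets(st.integers(0, 30), max_size=15),
           st.sets(st.integers(0, 30), max_size=15),
           st.integers(100, 130))
    @settings(deadline=None, derandomize=True)
    def test_monotonicity(self, a, b, new):
        # adding a shared item never decreases; an unshared one never increases
        base_j, base_t = jaccard(a, b), set_tanimoto(a, b)
        shared_j = jaccard(a | {new}, b | {new})
        assert shared_j >= base_j - 1e-12
        unshared_j = jaccard(a | {new}, b - {new})
        assert unshared_j <= base_j + 1e-12
        assert set_tanimoto(a | {new}, b | {new}) >= base_t - 1e-12


class TestJaccardNetwork:
    def _bn(self, matrix, n_entities):
        vocab = DrugVocabulary.from_ids([f"d{i}" for i in range(len(matrix))])
        ents = tuple(f"e{j}" for j in range(n_entities))
        return BipartiteNetwork(np.array(matrix, float), vocab, ents)

    def test_single_drug(self):
        net = jaccard_network(self._bn([[1, 0, 1]], 3))
        assert net.matrix.tolist() == [[1.0]]

    def test_identical_rows_offdiag_one(self):
        net = jaccard_network(self._bn([[1, 1, 0], [1, 1, 0]], 3))
        assert net.matrix[0, 1] == 1.0

    def test_matches_pairwise_brute_force(self):
        m = np.array([[1, 0, 1, 1], [0, 1, 1, 0], [1, 1, 0, 0]], float)
        bn = self._bn(m, 4)
        net = jaccard_network(bn)
        sets = bn.item_sets()
        for i in range(3):
            for j in range(3):
                assert net.matrix[i, j] == pytest.approx(jaccard(sets[i], sets[j]))

    def test_empty_row_gets_zero_diagonal(self):
        net = jaccard_network(self._bn([[1, 1], [0, 0]], 2))
        assert net.matrix[1, 1] == 0.0
        assert net.matrix[0, 1] == 0.0


class TestSmithWaterman:
    def test_self_similarity_is_one(self):
        assert sw_similarity("MKTAYIAKQR", "MKTAYIAKQR") == pytest.approx(1.0)

    def test_no_positive_alignment_is_zero(self):
        assert sw_similarity("AAAA", "CCCC") == 0.0

    def test_agrees_with_dp_oracle_on_random_pairs(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(aas), size=rng.integers(5, 31)))
            b = "".join(rng.choice(list(aas), size=rng.integers(5, 31)))
            assert sw_similarity(a, b) == pytest.approx(sw_similarity_dp(a, b), abs=1e-9)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            sw_similarity("", "MK")

    def test_invalid_residue_raises(self):
        with pytest.raises(ValueError, match="invalid"):
            sw_similarity("MK1", "MK")


class TestTargetSimilarity:
    def test_identical_singletons(self):
        assert target_similarity(["MKTAYIAKQR"], ["MKTAYIAKQR"]) == pytest.approx(1.0)

    def test_mean_over_cartesian_product(self):
        a = ["MKTAYIAKQR", "GGHHLLKK"]
        b = ["MKTAYLAKQR", "GGHHLLRR", "WWYYFF"]
        expected = np.mean([sw_similarity(x, y) for x in a for y in b])
        assert target_similarity(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        a, b = ["MKTAYIAKQR", "GGHHLLKK"], ["WWYYFF"]
        assert target_similarity(a, b) == pytest.approx(target_similarity(b, a))

    def test_empty_set_signals_missing_data(self):
        with pytest.raises(MissingDataError):
            target_similarity([], ["MK"])


class TestAtcSimilarity:
    def test_identical_code(self):
        assert atc_similarity(["N05AH04"], ["N05AH04"]) == 1.0

    def test_first_level_only(self):
        assert atc_similarity(["N05AH04"], ["N06AB03"]) == pytest.approx(0.2)

    def test_disjoint_first_level(self):
        assert atc_similarity(["N05AH04"], ["C07AB02"]) == 0.0

    def test_mean_over_code_pairs(self):
        val = atc_similarity(["N05AH04", "C07AB02"], ["N05AH04"])
        assert val == pytest.approx((1.0 + 0.0) / 2)

    def test_max_combination(self):
        assert atc_similarity(["N05AH04", "C07AB02"], ["N05AH04"], combine="max") == 1.0

    def test_malformed_code_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            atc_similarity(["N05AH"], ["N05AH04"])


class TestBuildSimilarityNetwork:
    def test_single_drug(self):
        vocab = DrugVocabulary.from_ids(["d0"])
        net = build_similarity_network(vocab, {"d0": np.array([1, 0, 1])}, tanimoto)
        assert net.matrix.tolist() == [[1.0]]

    def test_matches_pairwise_oracle(self, rng):
        vocab = DrugVocabulary.from_ids([f"d{i}" for i in range(5)])
        data = {d: (rng.random(16) < 0.4).astype(int) for d in vocab.ids}
        net = build_similarity_network(vocab, data, tanimoto)
        for i, di in enumerate(vocab.ids):
            for j, dj in enumerate(vocab.ids):
                expected = 1.0 if i == j else tanimoto(data[di], data[dj])
                assert net.matrix[i, j] == pytest.approx(expected)

    def test_vocabulary_permutation_permutes_matrix(self, rng):
        ids = [f"d{i}" for i in range(5)]
        data = {d: (rng.random(16) < 0.4).astype(int) for d in ids}
        net1 = build_similarity_network(DrugVocabulary.from_ids(ids), data, tanimoto)
        perm = ids[::-1]
        net2 = build_similarity_network(DrugVocabulary.from_ids(perm), data, tanimoto)
        p = [perm.index(d) for d in ids]
        assert np.allclose(net1.matrix, net2.matrix[np.ix_(p, p)])

    def test_missing_drug_gets_zero_row(self):
        vocab = DrugVocabulary.from_ids(["a", "b", "c"])
        data = {"a": np.array([1, 1]), "b": np.array([1, 0])}
        net = build_similarity_network(vocab, data, tanimoto)
        assert np.all(net.matrix[2] == 0.0)
        assert np.all(net.matrix[:, 2] == 0.0)


class TestNetworkInvariants:
    def test_all_small_networks_symmetric_unit_range(self, small_networks):
        homogeneous, _ = small_networks
        for net in homogeneous:
            m = net.matrix
            assert np.max(np.abs(m - m.T)) <= 1e-9
            assert m.min() >= 0.0 and m.max() <= 1.0 + 1e-12
            if net.is_similarity:
                assert np.all(np.isin(np.round(np.diag(m), 12), [0.0, 1.0]))
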