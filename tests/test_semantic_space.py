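import numpy as np
import pytest
from hypothesis import given, strategies as st

import seedlex.semantic_space as ss
from oracles import brute_force_counts, brute_force_vectors

CFG = ss.SpaceConfig(dimensionality=64, nonzeros=6, window=1, min_frequency=0, master_seed=9)


class TestIndexVectors:
    def test_deterministic_across_calls(self):
        a = ss.make_index_vector("薬", CFG)
        b = ss.make_index_vector("薬", CFG)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.signs, b.signs)

    def test_sign_balance_and_sparsity(self):
        cfg = ss.SpaceConfig(dimensionality=2000, nonzeros=10, master_seed=1)
        v = ss.make_index_vector("term", cfg).to_dense()
        assert v.sum() == 0
        assert np.abs(v).sum() == 10
        assert len(set(ss.make_index_vector("term", cfg).positions)) == 10

    def test_different_terms_or_seeds_differ(self):
        other = ss.make_index_vector("胃", CFG)
        assert not np.array_equal(ss.make_index_vector("薬", CFG).to_dense(), other.to_dense())
        reseeded = ss.SpaceConfig(**{**CFG.__dict__, "master_seed": 10})
        assert not np.array_equal(
            ss.make_index_vector("薬", CFG).to_dense(),
            ss.make_index_vector("薬", reseeded).to_dense(),
        )

    def test_odd_nonzeros_rejected(self):
        with pytest.raises(ValueError):
            ss.SpaceConfig(nonzeros=9)


class TestPermute:
    def test_right_rotation_definition(self):
        assert np.array_equal(ss.permute(np.array([1, 0, 0]), "right"), [0, 1, 0])

    def test_left_right_are_inverse(self):
        v = np.arange(8)
        assert np.array_equal(ss.permute(ss.permute(v, "left"), "right"), v)

    def test_norm_preserved(self):
        v = np.array([3.0, -1.0, 2.0, 0.5])
        assert np.linalg.norm(ss.permute(v, "left")) == pytest.approx(np.linalg.norm(v))


class TestFrequencies:
    def test_singleton_sentences_have_no_context(self):
        assert ss.count_frequencies([["a", "b"], ["a"]]) == {"a": 1, "b": 1}

    def test_empty_corpus(self):
        assert ss.count_frequencies([]) == {}

    def test_repeats_within_sentence(self):
        assert ss.count_frequencies([["a", "b", "a"]]) == {"a": 2, "b": 1}

    def test_count_isolated_variant(self):
        assert ss.count_frequencies([["a"]], count_isolated=True) == {"a": 1}


class TestCosine:
    def test_identity_opposite_orthogonal(self):
        v = np.array([1.0, 2.0, -1.0])
        assert ss.cosine(v, v) == pytest.approx(1.0)
        assert ss.cosine(v, -v) == pytest.approx(-1.0)
        assert ss.cosine(np.array([1, 0]), np.array([0, 1])) == 0.0

    def test_zero_vector_is_an_error_not_zero(self):
        with pytest.raises(ss.ZeroVectorError):
            ss.cosine(np.zeros(3), np.ones(3))


class TestBuildSpace:
    def test_two_unit_sentence_hand_accumulation(self):
        space = ss.build_space([["a", "b"]], CFG)
        ib = ss.make_index_vector("b", CFG).to_dense()
        ia = ss.make_index_vector("a", CFG).to_dense()
        assert np.array_equal(space.vector("a"), np.roll(ib, 1))
        assert np.array_equal(space.vector("b"), np.roll(ia, -1))

    def test_window_truncated_at_sentence_edges(self):
        cfg = ss.SpaceConfig(dimensionality=64, nonzeros=6, window=8, min_frequency=0, master_seed=9)
        space = ss.build_space([["a", "b", "c"]], cfg)
        ia = ss.make_index_vector("a", cfg).to_dense()
        ic = ss.make_index_vector("c", cfg).to_dense()
        assert np.array_equal(space.vector("b"), np.roll(ia, -1) + np.roll(ic, 1))

    def test_cutoff_empties_vector_table(self):
        cfg = ss.SpaceConfig(dimensionality=64, nonzeros=6, window=1, min_frequency=50, master_seed=9)
        space = ss.build_space([["a", "b"]], cfg)
        assert space.V == 0 and space.terms == ()
        assert space.frequencies == {"a": 1, "b": 1}

    def test_zero_sentences_error(self):
        with pytest.raises(ss.EmptyCorpusError):
            ss.build_space([], CFG)
        with pytest.raises(ss.EmptyCorpusError):
            ss.build_space([[]], CFG)

    def test_below_cutoff_units_still_contribute_context(self):
        cfg = ss.SpaceConfig(dimensionality=64, nonzeros=6, window=1, min_frequency=1, master_seed=9)
        space = ss.build_space([["a", "b"], ["a", "c"]], cfg)
        assert "a" in space and "b" not in space
        ib = ss.make_index_vector("b", cfg).to_dense()
        ic = ss.make_index_vector("c", cfg).to_dense()
        assert np.array_equal(space.vector("a"), np.roll(ib, 1) + np.roll(ic, 1))

    def test_entries_sum_to_zero_with_balanced_signs(self):
        corpus = [["a", "b", "c", "a"], ["b", "c", "d"], ["d", "a"]]
        space = ss.build_space(corpus, CFG)
        assert space.matrix.sum() == 0

    def test_corpus_doubling_doubles_vectors_and_keeps_cosines(self):
        corpus = [["a", "b", "c"], ["c", "d"]]
        one = ss.build_space(corpus, CFG)
        two = ss.build_space(corpus + corpus, CFG)
        for t in one.terms:
            assert np.array_equal(two.vector(t), 2 * one.vector(t))
        assert two.similarity("a", "c") == pytest.approx(one.similarity("a", "c"))

    def test_sentence_order_does_not_matter(self):
        corpus = [["a", "b"], ["c", "d", "a"], ["b", "c"]]
        fwd = ss.build_space(corpus, CFG)
        rev = ss.build_space(list(reversed(corpus)), CFG)
        assert fwd.terms == rev.terms
        assert np.array_equal(fwd.matrix, rev.matrix)

    @pytest.mark.parametrize("window", [1, 8])
    @pytest.mark.parametrize("use_permutation", [True, False])
    def test_matches_bruteforce_nested_loop_accumulation(self, window, use_permutation):
        cfg = ss.SpaceConfig(
            dimensionality=48,
            nonzeros=4,
            window=window,
            use_permutation=use_permutation,
            min_frequency=0,
            master_seed=4,
        )
        corpus = [
            ["薬", "を", "飲む"],
            ["頭", "痛い", "薬", "飲む", "寝る"],
            ["薬"],
            ["寝る", "頭"],
            ["飲む", "飲む", "薬"],
        ]
        space = ss.build_space(corpus, cfg)
        expected = brute_force_vectors(corpus, cfg)
        for term in space.terms:
            assert np.array_equal(space.vector(term), expected[term]), term
        assert space.frequencies == brute_force_counts(corpus)


class TestPersistence:
    def test_save_load_round_trip_bit_exact(self, tmp_path):
        corpus = [["a", "b", "c"], ["a", "c"], ["b", "a"]]
        space = ss.build_space(corpus, CFG)
        path = tmp_path / "space.txt"
        space.save(path)
        back = ss.SemanticSpace.load(path)
        assert back.config == space.config
        assert back.terms == space.terms
        assert back.frequencies == space.frequencies
        assert np.array_equal(back.matrix, space.matrix)
        # saving again is byte-identical
        path2 = tmp_path / "space2.txt"
        back.save(path2)
        assert path.read_bytes() == path2.read_bytes()
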