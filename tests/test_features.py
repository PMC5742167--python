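"""The eight QNA word features against hand values and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wordbeauty import (
    FrequencyTable,
    FeatureContext,
    LabelSetConfig,
    count_syllables,
    featurize,
    label_score,
    orthographic_n,
    relatedness,
    sonority_score,
    surprisal,
    word_similarity,
)
from wordbeauty.features import DEFAULT_SONORITY_SCALE, FeatureError, SonorityScale

from conftest import bfs_distance, hamming_neighbor_count, make_taxonomy

words_st = st.text(alphabet="abdeghilmnorstu", min_size=2, max_size=6)


class TestSyllables:
    @pytest.mark.parametrize(
        "word, n",
        [
            ("libelle", 3),       # Li-bel-le
            ("morgenröte", 4),    # Mor-gen-rö-te
            ("ei", 1),            # single diphthong
            ("aue", 2),           # au + e
            ("miauen", 3),        # mi-au-en
            ("baum", 1),
            ("mittsommernacht", 4),
        ],
    )
    def test_german_syllabification(self, word, n):
        assert count_syllables(word) == n

    def test_vowelless_input_rejected(self):
        with pytest.raises(FeatureError, match="vowel"):
            count_syllables("pfrt")

    def test_pluggable_backend_wins(self):
        assert count_syllables("libelle", backend=lambda w: 99) == 99


class TestSonority:
    def test_single_vowel_is_identity(self):
        assert sonority_score("a") == 5.0

    def test_hand_computed_mean(self):
        # (5 + 5 + 4) / 3
        assert sonority_score("aal") == pytest.approx(4.667, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(words_st)
    def test_composition_over_letters(self, word):
        """Word score equals the mean of its letters' scores."""
        per_letter = [sonority_score(c) for c in word]
        assert sonority_score(word) == pytest.approx(sum(per_letter) / len(per_letter))

    def test_every_german_letter_classified(self):
        for c in "abcdefghijklmnopqrstuvwxyzäöüß":
            assert DEFAULT_SONORITY_SCALE.rank_of(c) >= 1.0

    def test_unclassifiable_character_named(self):
        with pytest.raises(FeatureError, match="'9'"):
            sonority_score("a9")

    def test_non_monotone_scale_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            SonorityScale(ranks={"plosive": 3.0, "fricative": 2.0, "nasal": 3.5,
                                 "liquid": 4.0, "glide": 4.5, "vowel": 5.0})


class TestSurprisal:
    @pytest.mark.parametrize(
        "count, total_rest, bits",
        [(1024, 0, 0.0), (1, 1048575, 20.0), (8, 1016, 7.0)],
    )
    def test_hand_values(self, count, total_rest, bits):
        entries = {"ziel": count}
        if total_rest:
            entries["rest"] = total_rest
        assert surprisal("ziel", FrequencyTable(entries)) == pytest.approx(bits)

    def test_absent_word_rejected(self, toy_freq):
        with pytest.raises(FeatureError, match="absent"):
            surprisal("berg", toy_freq)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=1, max_value=10**6), st.integers(min_value=1, max_value=10**6))
    def test_strictly_decreasing_in_count(self, c1, c2):
        rest = 10**7
        s1 = surprisal("wal", FrequencyTable({"wal": c1, "rest": rest}))
        s2 = surprisal("wal", FrequencyTable({"wal": c2, "rest": rest}))
        if c1 < c2:
            assert s1 > s2
        elif c1 == c2:
            assert s1 == s2

    def test_growing_corpus_raises_every_surprisal(self):
        small = FrequencyTable({"aal": 3, "bau": 5})
        large = FrequencyTable({"aal": 3, "bau": 5, "unrelated": 100})
        assert surprisal("aal", large) > surprisal("aal", small)
        assert surprisal("bau", large) > surprisal("bau", small)


class TestOrthographicN:
    def test_self_excluded(self):
        assert orthographic_n("abc", FrequencyTable({"abc": 1})) == 0

    def test_hand_counted_neighborhood(self, toy_freq):
        # band, hund, hang, hans are each one substitution from hand
        assert orthographic_n("hand", toy_freq) == 4

    def test_absent_length_gives_zero(self, toy_freq):
        assert orthographic_n("zu", toy_freq) == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(words_st, min_size=1, max_size=40, unique=True), words_st)
    def test_matches_all_pairs_hamming_oracle(self, lexicon, word):
        freq = FrequencyTable({w: 1 for w in lexicon})
        assert orthographic_n(word, freq) == hamming_neighbor_count(word, lexicon)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(words_st, min_size=2, max_size=10, unique=True))
    def test_neighbor_relation_is_symmetric(self, lexicon):
        for w1 in lexicon:
            for w2 in lexicon:
                if w1 == w2:
                    continue
                counted_12 = orthographic_n(w1, FrequencyTable({w2: 1})) == 1
                counted_21 = orthographic_n(w2, FrequencyTable({w1: 1})) == 1
                assert counted_12 == counted_21


EDGES = [
    ("a", "root"), ("b", "root"), ("c", "a"), ("d", "a"), ("e", "b"),
    ("f", "c"), ("g", "c"), ("h", "e"),
]
LEMMAS = {
    "fichte": {"f"}, "ginster": {"g"}, "hafer": {"h"},
    "dorn": {"d"}, "rose": {"root"}, "farn": {"f"},
}


@pytest.fixture
def fixture_tax():
    return make_taxonomy(EDGES, LEMMAS)


def _oracle_relatedness(w1: str, w2: str) -> float:
    """BFS shortest-path relatedness on the fixture, computed independently."""
    depth = max(bfs_distance(EDGES, n, "root") for n in "abcdefgh")
    d = min(
        bfs_distance(EDGES, na, nb) for na in LEMMAS[w1] for nb in LEMMAS[w2]
    )
    return max(0.0, 1 - d / (2 * depth))


class TestRelatedness:
    def test_identity_is_maximal(self, fixture_tax):
        assert relatedness("fichte", "fichte", fixture_tax) == 1.0

    def test_shared_node_is_one(self, fixture_tax):
        assert relatedness("fichte", "farn", fixture_tax) == 1.0

    def test_sibling_leaves_match_bfs_oracle(self, fixture_tax):
        # leaves f and g under the common parent c
        assert relatedness("fichte", "ginster", fixture_tax) == pytest.approx(
            _oracle_relatedness("fichte", "ginster")
        )

    def test_all_pairs_match_bfs_oracle(self, fixture_tax):
        lemmas = list(LEMMAS)
        for i, wa in enumerate(lemmas):
            for wb in lemmas[i:]:
                assert relatedness(wa, wb, fixture_tax) == pytest.approx(
                    _oracle_relatedness(wa, wb)
                )

    @pytest.mark.parametrize(
        "pair",
        [("fichte", "ginster"), ("fichte", "hafer"), ("dorn", "rose"), ("ginster", "hafer")],
    )
    def test_symmetric_and_in_unit_interval(self, fixture_tax, pair):
        r_ab = relatedness(*pair, fixture_tax)
        r_ba = relatedness(*reversed(pair), fixture_tax)
        assert r_ab == r_ba
        assert 0.0 <= r_ab <= 1.0

    def test_unknown_lemma_rejected(self, fixture_tax):
        with pytest.raises(Exception, match="not in taxonomy"):
            relatedness("fichte", "geist", fixture_tax)


class TestWordSimilarity:
    def test_all_sharing_one_node_gives_one(self):
        tax = make_taxonomy([("a", "root")], {"ahorn": {"a"}, "ulme": {"a"}, "eibe": {"a"}})
        assert word_similarity("ahorn", ["ahorn", "ulme", "eibe"], tax) == 1.0

    def test_two_targets_reduces_to_single_relatedness(self, fixture_tax):
        sim = word_similarity("fichte", ["fichte", "hafer"], fixture_tax)
        assert sim == relatedness("fichte", "hafer", fixture_tax)

    def test_mean_of_pairwise_bfs_values(self, fixture_tax):
        targets = ["fichte", "ginster", "hafer", "dorn", "rose"]
        expected = np.mean(
            [_oracle_relatedness("fichte", t) for t in targets if t != "fichte"]
        )
        assert word_similarity("fichte", targets, fixture_tax) == pytest.approx(expected)

    def test_singleton_targets_rejected(self, fixture_tax):
        with pytest.raises(FeatureError):
            word_similarity("fichte", ["fichte"], fixture_tax)


class TestLabelScore:
    def test_mirrored_label_sets_give_zero(self, fixture_tax):
        # rose sits at the root, equidistant from the mirrored f/g attachments
        labels = LabelSetConfig("sym", ("fichte",), ("ginster",))
        assert label_score("rose", labels, fixture_tax) == pytest.approx(0.0)

    def test_positive_identity_dominates(self, fixture_tax):
        labels = LabelSetConfig("id", ("fichte",), ("hafer",))
        score = label_score("farn", labels, fixture_tax)  # farn shares node f with fichte
        assert score > 0
        pos = relatedness("farn", "fichte", fixture_tax)
        neg = relatedness("farn", "hafer", fixture_tax)
        assert score == pytest.approx(pos - neg)

    @pytest.mark.parametrize("word", ["fichte", "hafer", "rose"])
    def test_antisymmetric_under_pole_swap(self, fixture_tax, word):
        labels = LabelSetConfig("ab", ("ginster", "dorn"), ("hafer",))
        swapped = LabelSetConfig("ba", ("hafer",), ("ginster", "dorn"))
        assert label_score(word, labels, fixture_tax) == pytest.approx(
            -label_score(word, swapped, fixture_tax)
        )

    def test_unresolvable_labels_dropped_with_warning(self, fixture_tax):
        labels = LabelSetConfig("drop", ("fichte", "fehlt"), ("hafer",))
        with pytest.warns(UserWarning, match="dropped"):
            score = label_score("rose", labels, fixture_tax)
        clean = label_score("rose", LabelSetConfig("c", ("fichte",), ("hafer",)), fixture_tax)
        assert score == pytest.approx(clean)

    def test_empty_pole_after_drop_rejected(self, fixture_tax):
        labels = LabelSetConfig("bad", ("fehlt",), ("hafer",))
        with pytest.warns(UserWarning):
            with pytest.raises(FeatureError, match="no positive label"):
                label_score("rose", labels, fixture_tax)


class TestFeaturize:
    @pytest.fixture
    def ctx(self, fixture_tax):
        freq = FrequencyTable({w: 2 ** (i + 1) for i, w in enumerate(LEMMAS)})
        return FeatureContext(
            freq=freq,
            tax=fixture_tax,
            targets=list(LEMMAS),
            valence_labels=LabelSetConfig("v", ("fichte",), ("hafer",)),
            ap_labels=LabelSetConfig("ap", ("ginster",), ("dorn",)),
        )

    def test_vector_composes_sub_operations(self, ctx):
        vec = featurize("fichte", ctx)
        assert vec.n_syllables == count_syllables("fichte")
        assert vec.sonority == pytest.approx(sonority_score("fichte"))
        assert vec.length == 6
        assert vec.surprisal == pytest.approx(surprisal("fichte", ctx.freq))
        assert vec.neighborhood_n == orthographic_n("fichte", ctx.freq)
        assert vec.similarity == pytest.approx(
            word_similarity("fichte", ctx.targets, ctx.tax)
        )
        assert vec.valence == pytest.approx(label_score("fichte", ctx.valence_labels, ctx.tax))
        assert vec.ap == pytest.approx(label_score("fichte", ctx.ap_labels, ctx.tax))

    def test_length_is_letter_count(self, ctx, fixture_tax):
        fixture_tax.lemma_index["libelle"] = {"f"}
        ctx.freq = FrequencyTable({**dict(ctx.freq.entries), "libelle": 4})
        ctx.targets = list(ctx.targets) + ["libelle"]
        assert featurize("libelle", ctx).length == 7

    def test_deterministic(self, ctx):
        assert featurize("ginster", ctx) == featurize("ginster", ctx)

    def test_error_names_word(self, ctx):
        ctx.targets = list(ctx.targets) + ["fehlt"]
        with pytest.raises(FeatureError, match="fehlt"):
            featurize("fehlt", ctx)
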