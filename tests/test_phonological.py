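import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluencylab.phonological import (
    ClusterSpan,
    PronLexicon,
    RelationTag,
    count_switches,
    find_clusters,
    mean_cluster_size,
    pair_relation,
    score_phonological,
)
from fluencylab.sessions import FluencySession, TokenAnnotation

WORDS = ["find", "fire", "fry", "fly", "flip", "flop", "fair", "fare",
         "food", "fox", "fan", "fish", "four", "five", "fen", "fertile"]


class TestLexiconIO:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "lex.txt"
        p.write_text(";;; comment\nFIND  F AY1 N D\n")
        lex = PronLexicon.load(p)
        assert lex.get("find")[0].phones == ("F", "AY1", "N", "D")

    def test_homophone_entries(self, tmp_path):
        p = tmp_path / "lex.txt"
        p.write_text("FAIR  F EH1 R\nFARE  F EH1 R\n")
        lex = PronLexicon.load(p)
        assert lex.get("fair")[0].segments == lex.get("fare")[0].segments

    def test_variant_suffix(self, tmp_path):
        p = tmp_path / "lex.txt"
        p.write_text("FIRE  F AY1 ER0\nFIRE(1)  F AY1 R\n")
        lex = PronLexicon.load(p)
        assert len(lex.get("fire")) == 2

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "lex.txt"
        p.write_text(";;; nothing here\n")
        with pytest.raises(ValueError):
            PronLexicon.load(p)

    def test_malformed_line_skipped(self, tmp_path):
        p = tmp_path / "lex.txt"
        p.write_text("JUNK\nFIND  F AY1 N D\n")
        lex = PronLexicon.load(p)
        assert len(lex) == 1

    def test_save_roundtrip(self, tmp_path, pron_lex):
        out = tmp_path / "lex.txt"
        pron_lex.save(out)
        back = PronLexicon.load(out)
        assert back.words() == pron_lex.words()
        for w in back.words():
            assert {p.phones for p in back.get(w)} == {
                p.phones for p in pron_lex.get(w)
            }


class TestPairRelation:
    @pytest.mark.parametrize(
        "w1,w2,tag",
        [
            ("find", "fire", RelationTag.FIRST_TWO_PHONEMES),
            ("fair", "fare", RelationTag.HOMONYM),
            ("fry", "fly", RelationTag.RHYME),
            ("food", "fox", RelationTag.NONE),
            ("fire", "fry", RelationTag.NONE),
        ],
    )
    def test_worked_examples(self, pron_lex, w1, w2, tag):
        assert pair_relation(w1, w2, pron_lex) is tag

    def test_vowel_swap(self):
        # isolate the vowel-swap rule with words not sharing first phones
        lex = PronLexicon()
        lex.add("fip", ["F", "IH1", "P"])
        lex.add("fop", ["F", "AA1", "P"])
        assert pair_relation("fip", "fop", lex) is RelationTag.VOWEL_SWAP

    def test_flip_flop_related(self, pron_lex):
        # the vowel-swap pair also shares first two phonemes; precedence
        # reports the latter, but the pair must be related either way
        assert pair_relation("flip", "flop", pron_lex) is not RelationTag.NONE

    def test_identical_word_related_but_not_homonym(self, pron_lex):
        tag = pair_relation("fish", "fish", pron_lex)
        assert tag is not RelationTag.NONE
        assert tag is not RelationTag.HOMONYM

    def test_unknown_word_fallback(self, pron_lex):
        assert (
            pair_relation("fizzle", "fiddle", pron_lex, grapheme_fallback=True)
            is RelationTag.FIRST_TWO_PHONEMES
        )
        assert (
            pair_relation("fizzle", "fiddle", pron_lex, grapheme_fallback=False)
            is RelationTag.NONE
        )

    @given(st.sampled_from(WORDS), st.sampled_from(WORDS))
    def test_symmetry(self, w1, w2):
        from fluencylab.phonological import bundled_lexicon

        lex = bundled_lexicon()
        assert pair_relation(w1, w2, lex) is pair_relation(w2, w1, lex)


def oracle_clusters(tokens, lex):
    """Independent grouping: mark boundaries, then group via groupby."""
    if not tokens:
        return []
    related = [
        pair_relation(tokens[i], tokens[i + 1], lex) is not RelationTag.NONE
        for i in range(len(tokens) - 1)
    ]
    group_ids = [0]
    for r in related:
        group_ids.append(group_ids[-1] if r else group_ids[-1] + 1)
    spans = []
    for _, grp in itertools.groupby(range(len(tokens)), key=lambda i: group_ids[i]):
        idx = list(grp)
        spans.append((idx[0], idx[-1]))
    return spans


class TestClusters:
    def test_two_pairs(self, pron_lex):
        spans = find_clusters(["find", "fire", "fry", "fly"], pron_lex)
        assert [(s.start_index, s.end_index, s.size) for s in spans] == [
            (0, 1, 1),
            (2, 3, 1),
        ]

    def test_singleton_size_zero(self, pron_lex):
        spans = find_clusters(["fan"], pron_lex)
        assert [(s.start_index, s.end_index, s.size) for s in spans] == [(0, 0, 0)]

    def test_empty(self, pron_lex):
        assert find_clusters([], pron_lex) == []

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from(WORDS), min_size=1, max_size=8))
    def test_matches_oracle(self, words):
        from fluencylab.phonological import bundled_lexicon

        lex = bundled_lexicon()
        got = [(s.start_index, s.end_index) for s in find_clusters(words, lex)]
        assert got == oracle_clusters(words, lex)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from(WORDS), min_size=1, max_size=8))
    def test_partition_property(self, words):
        from fluencylab.phonological import bundled_lexicon

        spans = find_clusters(words, bundled_lexicon())
        covered = []
        for s in spans:
            covered.extend(range(s.start_index, s.end_index + 1))
        assert covered == list(range(len(words)))

    def test_unrelated_insertion_adds_one_switch(self, pron_lex):
        base = ["find", "fire", "fry", "fly"]
        spans0 = find_clusters(base, pron_lex)
        # "food" relates to neither fire nor fry
        spans1 = find_clusters(["find", "fire", "food", "fry", "fly"], pron_lex)
        assert count_switches(spans1) == count_switches(spans0) + 1
        assert sum(s.size for s in spans1) == sum(s.size for s in spans0)


class TestIndices:
    def test_mcs_two_pairs(self):
        spans = [ClusterSpan(0, 1), ClusterSpan(2, 3)]
        assert mean_cluster_size(spans) == 1.0

    def test_mcs_all_singletons(self):
        spans = [ClusterSpan(i, i) for i in range(3)]
        assert mean_cluster_size(spans) == 0.0

    def test_mcs_singletons_in_denominator(self):
        # 5 tokens: one two-word cluster + three singletons -> 1/4
        spans = [ClusterSpan(0, 1), ClusterSpan(2, 2), ClusterSpan(3, 3),
                 ClusterSpan(4, 4)]
        assert mean_cluster_size(spans) == 0.25

    def test_mcs_empty_is_missing(self):
        assert mean_cluster_size([]) is None

    def test_switches(self):
        assert count_switches([ClusterSpan(i, i) for i in range(3)]) == 2
        assert count_switches([ClusterSpan(0, 4)]) == 0
        assert count_switches([]) == 0

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.sampled_from(WORDS), min_size=1, max_size=8))
    def test_nos_mcs_invariants(self, words):
        from fluencylab.phonological import bundled_lexicon

        spans = find_clusters(words, bundled_lexicon())
        assert count_switches(spans) + 1 == len(spans)
        mcs = mean_cluster_size(spans)
        assert mcs <= max(s.size for s in spans)

    def test_score_includes_errors_and_repetitions(self, pron_lex):
        # errors/repetitions participate in clusters and switches
        toks = [TokenAnnotation(raw=w, norm=w) for w in ["find", "fire", "find"]]
        sess = FluencySession("p", tokens=toks)
        res = score_phonological(sess, pron_lex)
        assert len(res.spans) == 1  # one 3-word cluster
        assert res.num_switches == 0
        assert res.mean_cluster_size == 2.0
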