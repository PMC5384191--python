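import numpy as np
import pytest
from conftest import sw_oracle

from trajmine import (
    CutoffParams,
    align_local,
    annotate_text,
    decompound,
    load_vocabulary,
    score_cutoff,
)
from trajmine.vocab_annotator import VocabularyFormatError


class TestLoadVocabulary:
    def test_well_formed_tsv(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "concept_id\tgroup\tterm\thierarchy_path\n"
            "C1\tdisease\tCancer\tA/C1\n"
            "C2\tdrug\t Morphine \tB/C2\n"
            "C3\tprocedure\tbiopsy\t\n"
        )
        v = load_vocabulary(p)
        assert len(v.entries) == 3
        assert v.lookup("cancer")[0].concept_id == "C1"  # lower-cased
        assert v.lookup("morphine")[0].group == "drug"  # whitespace-normalized
        assert v.entries[0].hierarchy_path == ("A", "C1")

    def test_unknown_group_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("concept_id\tgroup\tterm\thierarchy_path\nC1\tfood\tapple\t\n")
        with pytest.raises(VocabularyFormatError, match="food"):
            load_vocabulary(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("concept_id\tterm\nC1\tcancer\n")
        with pytest.raises(VocabularyFormatError, match="group"):
            load_vocabulary(p)

    def test_duplicate_rows_listed(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text(
            "concept_id\tgroup\tterm\thierarchy_path\n"
            "C1\tdisease\tcancer\t\nC1\tdisease\tcancer\t\n"
        )
        with pytest.raises(VocabularyFormatError, match="duplicate"):
            load_vocabulary(p)


class TestDecompound:
    def test_greedy_longest_match(self, toy_vocab):
        splits = decompound("chemotherapy", toy_vocab)
        assert [(s, c) for s, c in splits] == [("chemo", "C003"),
                                               ("therapy", "C004")]

    @pytest.mark.parametrize("word", ["pain", "qqqqqqq"])
    def test_no_match_is_empty(self, word, toy_vocab):
        assert decompound(word, toy_vocab) == []

    def test_splits_are_ordered_nonoverlapping_subsequence(self, toy_vocab):
        word = "xxchemoyytherapyzz"
        splits = decompound(word, toy_vocab)
        assert [s for s, _ in splits] == ["chemo", "therapy"]
        # splits appear in order and each is >= min_split characters
        pos = 0
        for s, _ in splits:
            idx = word.index(s, pos)
            assert idx >= pos
            pos = idx + len(s)
            assert len(s) >= CutoffParams().min_split


class TestAlignLocal:
    def test_identical_strings_score_twice_length(self):
        a = align_local("gastritis", "gastritis")
        assert (a.score, a.n_matches, a.n_gaps) == (18, 9, 0)

    def test_single_substitution_drops_to_local_core(self):
        # local alignment discards the leading mismatch entirely: the best
        # alignment is the exact 5-char suffix, oracle-verified
        a = align_local("kancer", "cancer")
        assert (a.score, a.n_matches, a.n_mismatches, a.n_gaps) == (10, 5, 0, 0)
        assert sw_oracle("kancer", "cancer") == (10, 0)

    def test_interleaved_gaps_counted(self):
        a = align_local("abcd", "axbxcxd")
        assert a.n_gaps == 3  # caller's max_gaps=2 filter would reject this
        assert sw_oracle("abcd", "axbxcxd") == (a.score, 3)

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "x")

    def test_score_identity_and_oracle_agreement_random_pairs(self):
        rng = np.random.default_rng(42)
        alphabet = list("abcde")
        for _ in range(150):
            q = "".join(rng.choice(alphabet, size=rng.integers(1, 21)))
            t = "".join(rng.choice(alphabet, size=rng.integers(1, 21)))
            a = align_local(q, t)
            assert a.score == 2 * a.n_matches - a.n_mismatches - a.n_gaps
            assert (a.score, a.n_gaps) == sw_oracle(q, t)


class TestScoreCutoff:
    def test_constant_plane(self):
        p = CutoffParams(a=0, b=0, c=10)
        assert score_cutoff(3, 17, p) == 10

    def test_symmetry_when_coefficients_equal(self):
        p = CutoffParams(a=1.5, b=1.5, c=0.3)
        assert score_cutoff(4, 9, p) == pytest.approx(score_cutoff(9, 4, p))

    def test_monotone_in_lengths(self):
        p = CutoffParams()
        assert score_cutoff(10, 10, p) > score_cutoff(5, 5, p)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            score_cutoff(0, 5, CutoffParams())


class TestAnnotateText:
    def test_exact_match_has_no_errors(self, toy_vocab):
        ms = annotate_text("patient has cancer", "d1", toy_vocab)
        assert len(ms) == 1
        m = ms[0]
        assert (m.concept_id, m.alignment.n_mismatches, m.alignment.n_gaps) == (
            "C001", 0, 0)
        assert "patient has cancer"[m.char_span[0]:m.char_span[1]] == m.surface

    def test_fuzzy_match_found_at_default_cutoff(self, toy_vocab):
        # score 10 for the exact 5-char core clears 4*ln(6) ~ 7.2
        ms = annotate_text("patient has kancer", "d1", toy_vocab)
        assert [m.surface for m in ms] == ["kancer"]
        assert ms[0].concept_id == "C001"

    def test_empty_document(self, toy_vocab):
        assert annotate_text("", "d1", toy_vocab) == []

    def test_decompound_mentions_flagged(self, toy_vocab):
        ms = annotate_text("started chemotherapy", "d1", toy_vocab)
        assert [(m.surface, m.via_decompound) for m in ms] == [
            ("chemo", True), ("therapy", True)]

    def test_raising_intercept_never_adds_mentions(self, toy_vocab):
        doc = "kancer gastritis chemotherapy nauzea xylophone"
        counts = [
            len(annotate_text(doc, "d", toy_vocab, CutoffParams(c=c)))
            for c in (0.0, 2.0, 5.0, 50.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAlignmentProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    words = st.text(alphabet="abcd", min_size=1, max_size=12)

    @given(q=words, t=words)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_score_identity_and_span_bounds(self, q, t):
        a = align_local(q, t)
        assert a.score == 2 * a.n_matches - a.n_mismatches - a.n_gaps
        assert a.score >= 0
        qs, qe = a.query_span
        ts, te = a.target_span
        assert 0 <= qs <= qe <= len(q)
        assert 0 <= ts <= te <= len(t)
        assert (a.score, a.n_gaps) == sw_oracle(q, t)

    @given(word=st.text(alphabet="abcdefgh", min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_decompound_splits_are_vocabulary_subsequences(self, word):
        from trajmine import Vocabulary, VocabEntry

        toy_vocab = Vocabulary([
            VocabEntry("C003", "drug", "chemo"),
            VocabEntry("C004", "procedure", "therapy"),
            VocabEntry("C001", "disease", "cancer"),
        ])
        splits = decompound(word, toy_vocab)
        pos = 0
        for sub, _ in splits:
            idx = word.lower().index(sub, pos)
            assert idx >= pos
            pos = idx + len(sub)
            assert len(sub) >= 5
            assert toy_vocab.lookup(sub)
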