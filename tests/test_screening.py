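"""Fuzzy-matching and screening-gate behaviour, checked against
independent oracles: edlib for edit distance, exhaustive generate-and-
filter for variant enumeration, and a naive all-positions scan for
substring matching."""

from __future__ import annotations

import datetime as dt
import itertools

import edlib
import pytest
from hypothesis import given
from hypothesis import strategies as st

from soclisten.corpus_io import NormalizedRecord
from soclisten.screening import (
    CESSATION_KEYWORDS,
    SEED_TERM,
    TERM_VARIANTS,
    ScreeningCriteria,
    edit_distance,
    enumerate_variants,
    match_cessation,
    match_context,
    match_term,
    screen_corpus,
    within_window,
)


def _rec(text: str, subreddit: str = "sublocade", rid: str = "x1",
         date: dt.date = dt.date(2020, 6, 1)) -> NormalizedRecord:
    return NormalizedRecord(
        record_id=rid, author_id="a1", created_date=date,
        subreddit=subreddit, text=text, kind="comment",
    )


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("sublocade", "sublocade", 0),
            ("sublocade", "subocade", 1),  # deletion variant from the list
            ("kitten", "sitting", 3),
            ("", "", 0),
            ("", "abc", 3),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_case_insensitive_flag(self):
        assert edit_distance("Sublocade", "sublocade") == 1
        assert edit_distance("Sublocade", "sublocade", case_insensitive=True) == 0

    @given(st.text(alphabet="abcde", max_size=12), st.text(alphabet="abcde", max_size=12))
    def test_agrees_with_edlib(self, a, b):
        """Dual route: our DP vs the edlib alignment library."""
        expected = 0 if a == b == "" else edlib.align(a, b)["editDistance"]
        assert edit_distance(a, b) == expected

    @given(st.text(max_size=10), st.text(max_size=10))
    def test_symmetric(self, a, b):
        assert edit_distance(a, b) == edit_distance(b, a)


class TestEnumerateVariants:
    def test_zero_distance_is_identity(self):
        assert enumerate_variants("ab", 0, "ab") == {"ab"}

    def test_two_letter_neighborhood(self):
        got = enumerate_variants("ab", 1, "ab")
        assert got == {"ab", "a", "b", "aa", "bb", "aab", "aba", "abb", "bab"}

    @pytest.mark.parametrize("term,alphabet,d", [
        ("ab", "abc", 1),
        ("abc", "abc", 1),
        ("aba", "ab", 2),
        ("x", "xyz", 2),
        ("abca", "abcd", 1),
    ])
    def test_matches_exhaustive_brute_force(self, term, alphabet, d):
        """Oracle: every string up to len(term)+d over the alphabet,
        filtered by edlib distance."""
        universe = (
            "".join(p)
            for k in range(len(term) + d + 1)
            for p in itertools.product(alphabet, repeat=k)
        )
        expected = {
            s for s in universe
            if (edlib.align(term, s)["editDistance"] if (term or s) else 0) <= d
        }
        assert enumerate_variants(term, d, alphabet) == expected

    def test_seed_term_neighborhood(self):
        """All-distinct 9-letter seed over a–z: 25n substitutions + n
        deletions + 26(n+1)−n distinct insertions + the seed = 486."""
        got = enumerate_variants(SEED_TERM, 1)
        assert len(got) == 486
        assert all(edlib.align(SEED_TERM, s)["editDistance"] <= 1 for s in got)
        for v in TERM_VARIANTS:
            assert v in got

    def test_size_guard(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_variants("sublocade", 3, cap=10_000)


class TestCriteria:
    def test_every_listed_variant_within_distance_one(self, criteria):
        assert len(criteria.explicit_variants) == 20
        for v in criteria.explicit_variants:
            assert edit_distance(criteria.seed_term, v, case_insensitive=True) <= 1

    def test_rejects_out_of_distance_variant(self):
        with pytest.raises(ValueError, match="distance"):
            ScreeningCriteria(explicit_variants=("sublocade", "suboxone"))

    def test_rejects_inverted_window(self):
        with pytest.raises(ValueError):
            ScreeningCriteria(
                window_start=dt.date(2022, 1, 1), window_end=dt.date(2018, 1, 1)
            )


class TestMatchTerm:
    def test_plural_variant_matches(self, criteria):
        res = match_term("My Sublocades are working", criteria)
        assert res.matched
        assert "sublocades" in {kw for kw, _ in res.matched_strings}

    def test_empty_text(self, criteria):
        assert not match_term("", criteria).matched

    def test_non_variant_drug_name_does_not_match(self, criteria):
        text = "suboxone only today"
        assert not match_term(text, criteria).matched
        # verify via the naive oracle that no listed string occurs anywhere
        low = text.lower()
        assert all(
            low[i : i + len(v)] != v
            for v in criteria.explicit_variants
            for i in range(len(low))
        )

    def test_token_mode_catches_unlisted_misspelling(self, criteria):
        tok = ScreeningCriteria(match_mode="generative_token")
        # distance-1 misspelling not on the explicit list
        assert not match_term("on xublocade now", criteria).matched
        assert match_term("on xublocade now", tok).matched

    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=60))
    def test_case_invariance(self, text):
        c = ScreeningCriteria()
        assert match_term(text, c).matched == match_term(text.upper(), c).matched


class TestMatchContextAndWindow:
    @pytest.mark.parametrize("sub,expected", [
        ("sublocade", True), ("opiates", False), ("suboxone", False),
    ])
    def test_context(self, criteria, sub, expected):
        assert match_context(_rec("hello", subreddit=sub), criteria) is expected

    def test_context_is_case_folded_at_normalization(self, criteria):
        rec = _rec("hello", subreddit="Sublocade".lower())
        assert match_context(rec, criteria)

    @pytest.mark.parametrize("date,expected", [
        (dt.date(2018, 3, 1), True),   # first day in
        (dt.date(2018, 2, 28), False),  # day before
        (dt.date(2022, 8, 31), True),   # last day in
        (dt.date(2022, 9, 1), False),
    ])
    def test_window_inclusive(self, criteria, date, expected):
        assert within_window(date, criteria) is expected


class TestMatchCessation:
    def test_taper_matches(self, criteria):
        assert match_cessation("planning to taper off next month", criteria).matched

    def test_substring_false_positive_surface(self, criteria):
        # "last" matches in substring mode even in a non-cessation sense
        res = match_cessation("at last I feel normal", criteria)
        assert res.matched
        assert ("last", 3) in res.matched_strings

    def test_no_keyword(self, criteria):
        text = "no relevant words here"
        assert not match_cessation(text, criteria).matched
        low = text.lower()
        assert all(
            low[i : i + len(k)] != k
            for k in CESSATION_KEYWORDS
            for i in range(len(low))
        )

    def test_token_mode_is_stricter(self, criteria):
        assert match_cessation("the finale was wild", criteria).matched
        assert not match_cessation(
            "the finale was wild", criteria, token_mode=True
        ).matched


class TestScreenCorpus:
    def test_all_pass(self, criteria):
        recs = [
            _rec("sublocade taper soon", rid=f"r{i}") for i in range(4)
        ]
        sc = screen_corpus(recs, criteria)
        assert [c.n_out for c in sc.stage_counts] == [4, 4, 4, 4]
        assert all(
            r.match_criteria
            >= {"term_keyword", "subreddit_context", "cessation_keyword"}
            for r in sc.records
        )

    def test_duplicate_removed_at_stage_two(self, criteria):
        rec = _rec("sublocade taper", rid="dup")
        sc = screen_corpus([rec, rec], criteria)
        counts = {c.stage: c for c in sc.stage_counts}
        assert counts["deduplicate"].n_removed == 1
        assert len(sc.records) == 1

    def test_empty_input(self, criteria):
        sc = screen_corpus([], criteria)
        assert sc.records == []
        assert all(c.n_in == c.n_out == 0 for c in sc.stage_counts)

    def test_idempotent(self, criteria, small_normalized):
        once = screen_corpus(small_normalized, criteria)
        twice = screen_corpus(once.records, criteria)
        assert [r.record_id for r in twice.records] == [
            r.record_id for r in once.records
        ]
        assert all(c.n_removed == 0 for c in twice.stage_counts)

    def test_recovers_planted_truth(self, criteria, small_corpus, small_normalized):
        _, _, truth, _ = small_corpus
        sc = screen_corpus(small_normalized, criteria)
        expected = {
            t.record_id for t in truth.records if t.passes_all_gates
        }
        assert {r.record_id for r in sc.records} == expected
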