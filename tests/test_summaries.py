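"""Descriptive-statistics operations."""

from __future__ import annotations

import datetime as dt
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from soclisten.codebook import Annotation
from soclisten.corpus_io import NormalizedRecord
from soclisten.summaries import (
    UndefinedPercentageError,
    author_stats,
    dose_distributions,
    percentage,
    summary_report,
)


def _rec(rid: str, author: str, sub: str = "sublocade") -> NormalizedRecord:
    return NormalizedRecord(
        record_id=rid, author_id=author, created_date=dt.date(2020, 1, 1),
        subreddit=sub, text="t", kind="comment",
    )


class TestPercentage:
    @pytest.mark.parametrize("num,den,expected", [
        (1179, 2692, 43.8),
        (102, 1179, 8.7),
        (2968, 3041, 97.6),
        (976, 1179, 82.8),
        (203, 1179, 17.2),
        (0, 100, 0.0),
        (1, 8, 12.5),
    ])
    def test_published_style_rounding(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_up_at_the_boundary(self):
        assert percentage(1, 16, decimals=2) == 6.25
        assert percentage(1, 16, decimals=1) == 6.3  # 6.25 rounds up, not to even

    def test_zero_denominator(self):
        with pytest.raises(UndefinedPercentageError):
            percentage(1, 0)

    @given(st.integers(0, 5000), st.integers(1, 5000))
    def test_complement_sums_to_about_100(self, a, b):
        a = min(a, b)
        assert 99.9 <= percentage(a, b) + percentage(b - a, b) <= 100.1


class TestAuthorStats:
    def test_hand_computed_sample_sd(self):
        recs = [_rec("r1", "A"), _rec("r2", "A"), _rec("r3", "A"), _rec("r4", "B")]
        s = author_stats(recs)
        assert s.n_authors == 2
        assert s.mean == 2.0
        assert s.sd == pytest.approx(math.sqrt(2))
        assert (s.min, s.max) == (1, 3)

    def test_single_author_sd_flagged(self):
        s = author_stats([_rec(f"r{i}", "A") for i in range(4)])
        assert s.mean == 4.0 and s.sd == 0.0 and not s.sd_defined

    def test_empty(self):
        s = author_stats([])
        assert s.n_authors == 0 and not s.sd_defined

    def test_generator_counts_recovered(self, small_corpus, small_normalized):
        _, _, truth, _ = small_corpus
        from soclisten.sampling_dedup import deduplicate

        deduped, _ = deduplicate(small_normalized)
        s = author_stats(deduped)
        assert s.counts == {a: c for a, c in truth.per_author_counts.items()}


class TestDoseDistributions:
    def test_sequence_and_final_counts(self):
        anns = [
            Annotation(record_id="a", course_of_treatment=[300]),
            Annotation(record_id="b", course_of_treatment=[300]),
            Annotation(record_id="c", course_of_treatment=[100]),
        ]
        d = dose_distributions(anns)
        assert d.sequence_counts == {"300": 2, "100": 1}
        assert d.final_dose_mode == 300

    def test_final_only_reports_pool_into_final_not_sequence(self):
        anns = [
            Annotation(record_id="a", course_of_treatment=[300, 100]),
            Annotation(record_id="b", final_dosage=100),
        ]
        d = dose_distributions(anns)
        assert d.n_courses == 1
        assert d.final_dose_counts == {100: 2}
        assert d.n_final_dose_reports == 2

    def test_count_statistics(self):
        anns = [
            Annotation(record_id=str(i), number_of_doses=k)
            for i, k in enumerate([1, 3, 3, 5])
        ]
        d = dose_distributions(anns)
        assert d.n_doses_mean == 3.0
        assert d.n_doses_median == 3.0
        # IQR with linear interpolation: Q1=2.5, Q3=3.5
        assert d.n_doses_iqr == pytest.approx(1.0)

    def test_planted_final_dose_mode_recovered(self, small_corpus):
        _, _, _, gold = small_corpus
        d = dose_distributions(gold)
        assert d.final_dose_mode == 100


class TestSummaryReport:
    def test_denominator_chain_and_traceability(self):
        sampled = [_rec(f"r{i}", f"a{i % 3}") for i in range(8)]
        screened = sampled + [_rec("r8", "a0")]
        anns = (
            [Annotation(record_id=f"r{i}", sublocade=1, any_cessation=1,
                        intentional_cessation=1, cessation_timing="retrospective")
             for i in range(3)]
            + [Annotation(record_id="r3", sublocade=1, any_cessation=1,
                          circumstantial_cessation=1, cessation_timing="planned",
                          postcourse_withdrawal=1)]
            + [Annotation(record_id=f"r{i}", sublocade=1) for i in (4, 5)]
            + [Annotation(record_id="r6")]
        )
        s = summary_report(screened, sampled, anns)
        assert s.n_total == 9 and s.n_sampled == 8
        assert (s.n_sublocade.n, s.n_sublocade.denominator) == (6, 8)
        assert s.n_sublocade.percent == 75.0
        assert (s.n_cessation.n, s.n_cessation.denominator) == (4, 6)
        assert (s.n_retrospective.n, s.n_planned.n) == (3, 1)
        assert s.n_withdrawal.n == 1
        assert s.n_withdrawal.denominator == 4

    def test_all_zero_annotations(self):
        sampled = [_rec("r0", "a")]
        s = summary_report(sampled, sampled, [Annotation(record_id="r0")])
        assert s.n_sublocade.n == 0 and s.n_sublocade.percent == 0.0
        assert s.n_cessation.percent is None  # denominator zero: undefined

    def test_subreddit_distribution_sums_to_sample(self):
        sampled = [_rec(f"r{i}", "a", sub="sublocade" if i < 7 else "opiates")
                   for i in range(10)]
        s = summary_report(sampled, sampled, [])
        assert sum(cp.n for cp in s.subreddit_distribution.values()) == 10
        assert s.subreddit_distribution["sublocade"].percent == 70.0

    def test_text_rendering_contains_headline_numbers(self, small_corpus,
                                                      small_normalized):
        _, _, _, gold = small_corpus
        from soclisten.sampling_dedup import SamplePlan, draw_sample, deduplicate
        from soclisten.screening import ScreeningCriteria, screen_corpus

        screened = screen_corpus(small_normalized, ScreeningCriteria())
        sampled = draw_sample(screened.records, SamplePlan(fraction=0.5, seed=1))
        ids = {r.record_id for r in sampled}
        s = summary_report(screened.records, sampled,
                           [a for a in gold if a.record_id in ids])
        text = s.to_text()
        assert str(s.n_sampled) in text
        assert "r/sublocade" in text
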