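"""Descriptive statistics over the screened, sampled, annotated corpus.

All percentages are half-up rounded at one decimal, with the
numerator/denominator pair retained next to each percent so every printed
figure is traceable.  Dispersion statistics use the sample convention
(n − 1 denominator for SD, linear-interpolation quantiles, IQR = Q3 − Q1).
Author-level aggregates treat the obfuscated account token as the unit of
analysis; one person holding several accounts is counted several times —
an inherited property of the data source, reported as-is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .codebook import Annotation, format_course
from .corpus_io import NormalizedRecord

__all__ = [
    "percentage",
    "author_stats",
    "dose_distributions",
    "summary_report",
    "AuthorStats",
    "DoseSummary",
    "CorpusSummary",
]


class UndefinedPercentageError(ZeroDivisionError):
    pass


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Half-up rounded percentage, e.g. (1179, 2692) -> 43.8."""
    if denominator <= 0:
        raise UndefinedPercentageError(
            f"percentage undefined for denominator {denominator}"
        )
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must satisfy 0 <= numerator <= denominator")
    from decimal import Decimal

    return round_half_up(Decimal(numerator) * 100 / Decimal(denominator), decimals)


@dataclass
class AuthorStats:
    n_authors: int
    n_records: int
    mean: float
    sd: float
    min: int
    max: int
    sd_defined: bool = True
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_authors": self.n_authors,
            "n_records": self.n_records,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "sd_defined": self.sd_defined,
        }


def author_stats(records: Sequence[NormalizedRecord]) -> AuthorStats:
    """Per-account record counts: unique authors, mean, sample SD, range.

    With a single author the sample SD is undefined; it is reported as 0.0
    with ``sd_defined`` cleared.
    """
    if not records:
        return AuthorStats(0, 0, 0.0, 0.0, 0, 0, sd_defined=False)
    counts = Counter(r.author_id for r in records)
    vals = np.array(list(counts.values()), dtype=float)
    sd_defined = len(vals) > 1
    return AuthorStats(
        n_authors=len(counts),
        n_records=len(records),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if sd_defined else 0.0,
        min=int(vals.min()),
        max=int(vals.max()),
        sd_defined=sd_defined,
        counts=dict(counts),
    )


@dataclass
class DoseSummary:
    """Dose-sequence and final-dose distributions.

    The sequence table counts distinct full courses among annotations that
    report one; the final-dose table additionally pools annotations that
    reported only their final dose.  Number-of-doses statistics are over
    annotations with an explicit count or a full course.
    """

    sequence_counts: dict[str, int]
    final_dose_counts: dict[int, int]
    final_dose_mode: Optional[int]
    n_courses: int
    n_final_dose_reports: int
    n_doses_mean: Optional[float] = None
    n_doses_sd: Optional[float] = None
    n_doses_median: Optional[float] = None
    n_doses_iqr: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "sequence_counts": dict(self.sequence_counts),
            "final_dose_counts": {str(k): v for k, v in self.final_dose_counts.items()},
            "final_dose_mode": self.final_dose_mode,
            "n_courses": self.n_courses,
            "n_final_dose_reports": self.n_final_dose_reports,
            "n_doses_mean": self.n_doses_mean,
            "n_doses_sd": self.n_doses_sd,
            "n_doses_median": self.n_doses_median,
            "n_doses_iqr": self.n_doses_iqr,
        }


def dose_distributions(annotations: Sequence[Annotation]) -> DoseSummary:
    seq_counter: Counter[str] = Counter()
    final_counter: Counter[int] = Counter()
    n_dose_counts: list[int] = []
    for a in annotations:
        course = a.course_of_treatment
        if course:
            seq_counter[format_course(course)] += 1
            final_counter[course[-1]] += 1
        elif a.final_dosage is not None:
            final_counter[a.final_dosage] += 1
        if a.number_of_doses is not None:
            n_dose_counts.append(a.number_of_doses)
        elif course:
            n_dose_counts.append(len(course))

    mode = None
    if final_counter:
        # deterministic tie-break: larger count first, then smaller dose
        mode = min(final_counter, key=lambda d: (-final_counter[d], d))

    summary = DoseSummary(
        sequence_counts=dict(seq_counter),
        final_dose_counts=dict(final_counter),
        final_dose_mode=mode,
        n_courses=sum(seq_counter.values()),
        n_final_dose_reports=sum(final_counter.values()),
    )
    if n_dose_counts:
        arr = np.array(n_dose_counts, dtype=float)
        summary.n_doses_mean = float(arr.mean())
        summary.n_doses_sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        summary.n_doses_median = float(np.median(arr))
        q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
        summary.n_doses_iqr = float(q3 - q1)
    return summary


@dataclass
class CountPercent:
    n: int
    denominator: int
    percent: Optional[float]

    def to_dict(self) -> dict:
        return {"n": self.n, "denominator": self.denominator, "percent": self.percent}


def _cp(n: int, denom: int) -> CountPercent:
    return CountPercent(n, denom, percentage(n, denom) if denom > 0 else None)


@dataclass
class CorpusSummary:
    """All headline descriptive statistics of one pipeline run."""

    n_total: int
    n_sampled: int
    n_sublocade: CountPercent
    n_cessation: CountPercent
    n_retrospective: CountPercent
    n_planned: CountPercent
    n_withdrawal: CountPercent
    n_craving: int
    author: AuthorStats
    subreddit_distribution: dict[str, CountPercent]
    doses: DoseSummary

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_sampled": self.n_sampled,
            "n_sublocade": self.n_sublocade.to_dict(),
            "n_cessation": self.n_cessation.to_dict(),
            "n_retrospective": self.n_retrospective.to_dict(),
            "n_planned": self.n_planned.to_dict(),
            "n_withdrawal": self.n_withdrawal.to_dict(),
            "n_craving": self.n_craving,
            "author_stats": self.author.to_dict(),
            "subreddit_distribution": {
                k: v.to_dict() for k, v in self.subreddit_distribution.items()
            },
            "dose_distributions": self.doses.to_dict(),
        }

    def to_text(self) -> str:
        lines = [
            "Corpus summary",
            "==============",
            f"Screened unique records      : {self.n_total}",
            f"Coded sample                 : {self.n_sampled}",
        ]

        def fmt(label: str, cp: CountPercent) -> str:
            pct = "n/a" if cp.percent is None else f"{cp.percent}%"
            return (
                f"{label:<29}: {cp.n} ({pct} of {cp.denominator})"
            )

        lines += [
            fmt("Product referent confirmed", self.n_sublocade),
            fmt("Cessation referenced", self.n_cessation),
            fmt("  retrospective", self.n_retrospective),
            fmt("  planned", self.n_planned),
            fmt("Opioid withdrawal", self.n_withdrawal),
            f"Opioid craving               : {self.n_craving}",
            "",
            f"Unique accounts              : {self.author.n_authors}",
            (
                f"Records per account          : mean {round_half_up(self.author.mean, 1)}, "
                f"SD {round_half_up(self.author.sd, 1)}, "
                f"range {self.author.min}-{self.author.max}"
            ),
            "",
            "Top subreddits:",
        ]
        top = sorted(
            self.subreddit_distribution.items(), key=lambda kv: (-kv[1].n, kv[0])
        )[:5]
        for name, cp in top:
            lines.append(f"  r/{name:<20} {cp.n} ({cp.percent}%)")
        d = self.doses
        lines += [
            "",
            f"Full dose courses reported   : {d.n_courses}",
            f"Final-dose reports (pooled)  : {d.n_final_dose_reports}",
            f"Most common final dose       : "
            + ("n/a" if d.final_dose_mode is None else f"{d.final_dose_mode} mg"),
        ]
        if d.n_doses_mean is not None:
            lines.append(
                f"Doses before cessation       : mean {round_half_up(d.n_doses_mean, 1)}, "
                f"SD {round_half_up(d.n_doses_sd, 1)}, "
                f"median {d.n_doses_median:g}, IQR {d.n_doses_iqr:g}"
            )
        return "\n".join(lines) + "\n"


def summary_report(
    screened_records: Sequence[NormalizedRecord],
    sampled_records: Sequence[NormalizedRecord],
    annotations: Sequence[Annotation],
) -> CorpusSummary:
    """Assemble the full descriptive summary.

    Denominator chain: product-referent percent is over the coded sample;
    cessation percent over confirmed referents; timing and withdrawal
    percents over cessation records.
    """
    if not screened_records and sampled_records:
        raise ValueError("sampled records supplied without a screened corpus")
    ann = list(annotations)
    n_sampled = len(sampled_records)
    n_subl = sum(a.sublocade == 1 for a in ann)
    cess = [a for a in ann if a.any_cessation == 1]
    n_cess = len(cess)
    n_retro = sum(a.cessation_timing == "retrospective" for a in cess)
    n_plan = sum(a.cessation_timing == "planned" for a in cess)
    n_wd = sum(
        a.within_course_withdrawal == 1 or a.postcourse_withdrawal == 1 for a in cess
    )
    n_crave = sum(a.opioid_craving == 1 for a in ann)

    sub_counter = Counter(r.subreddit for r in sampled_records)
    sub_dist = {
        name: _cp(n, n_sampled)
        for name, n in sorted(sub_counter.items(), key=lambda kv: (-kv[1], kv[0]))
    }

    return CorpusSummary(
        n_total=len(screened_records),
        n_sampled=n_sampled,
        n_sublocade=_cp(n_subl, n_sampled),
        n_cessation=_cp(n_cess, n_subl),
        n_retrospective=_cp(n_retro, n_cess),
        n_planned=_cp(n_plan, n_cess),
        n_withdrawal=_cp(n_wd, n_cess),
        n_craving=n_crave,
        author=author_stats(list(sampled_records)),
        subreddit_distribution=sub_dist,
        doses=dose_distributions(ann),
    )
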