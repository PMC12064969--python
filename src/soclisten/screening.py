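"""Inclusion criteria for drug-mention screening of a social-media corpus.

A record enters the study corpus if it refers to the target product —
either lexically (its text contains the brand name or a close misspelling)
or contextually (it was posted in the product's dedicated subreddit) — and,
after deduplication, if it also contains a treatment-cessation keyword and
falls inside the study's date window.  The stages are applied in that fixed
order and per-stage record counts are reported as an attrition table.

Fuzzy brand-name matching is operationalized as case-insensitive Levenshtein
distance: the default keyword list is the 20 strings within distance 1 of
"sublocade" that were observed in the wild, and an exhaustive distance-``d``
variant enumerator is provided for sensitivity analyses.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import NormalizedRecord

__all__ = [
    "SEED_TERM",
    "TERM_VARIANTS",
    "CESSATION_KEYWORDS",
    "ScreeningCriteria",
    "MatchResult",
    "ScreenedCorpus",
    "edit_distance",
    "enumerate_variants",
    "match_term",
    "match_context",
    "match_cessation",
    "within_window",
    "screen_corpus",
]

SEED_TERM = "sublocade"

#: The 20 observed brand-name strings used for keyword inclusion.  Every
#: entry is within case-insensitive Levenshtein distance 1 of the seed term.
TERM_VARIANTS: tuple[str, ...] = (
    "sublocade",
    "subloccade",
    "sublacade",
    "sulocade",
    "subblocade",
    "sublucade",
    "sublockade",
    "sublocate",
    "subloocade",
    "sublcocade",
    "sublocode",
    "suublocade",
    "subloclade",
    "sublicade",
    "sublocades",
    "subclocade",
    "sublocane",
    "sublocadr",
    "sublocase",
    "subocade",
)

#: Keywords marking possible discussion of stopping treatment.
CESSATION_KEYWORDS: tuple[str, ...] = (
    "taper",
    "stop",
    "final",
    "quit",
    "last",
    "reduce",
    "decrease",
    "discontinue",
)

#: Rule labels recorded in a retained record's match provenance.
TERM_KEYWORD = "term_keyword"
SUBREDDIT_CONTEXT = "subreddit_context"
CESSATION_KEYWORD = "cessation_keyword"


def edit_distance(a: str, b: str, case_insensitive: bool = False) -> int:
    """Levenshtein distance between two strings.

    Unit-cost single-character insertions, deletions and substitutions;
    symmetric; zero iff the strings are equal (after ASCII case folding when
    ``case_insensitive`` is set).
    """
    if case_insensitive:
        a, b = a.lower(), b.lower()
    if a == b:
        return 0
    if len(a) < len(b):  # iterate over the longer string, row = shorter
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion from a
                cur[j - 1] + 1,  # insertion into a
                prev[j - 1] + (ca != cb),  # substitution / match
            )
        prev = cur
    return prev[-1]


def _neighbors(term: str, alphabet: Sequence[str]) -> set[str]:
    """All strings at Levenshtein distance <= 1 of ``term`` (term included)."""
    out = {term}
    n = len(term)
    for i in range(n):
        out.add(term[:i] + term[i + 1 :])  # deletion
        for c in alphabet:
            out.add(term[:i] + c + term[i + 1 :])  # substitution
    for i in range(n + 1):
        for c in alphabet:
            out.add(term[:i] + c + term[i:])  # insertion
    return out


DEFAULT_VARIANT_CAP = 500_000


def enumerate_variants(
    term: str,
    max_distance: int,
    alphabet: Iterable[str] = "abcdefghijklmnopqrstuvwxyz",
    cap: int = DEFAULT_VARIANT_CAP,
) -> set[str]:
    """Exactly the set of strings within ``max_distance`` edits of ``term``.

    Computed by iterated expansion of the distance-1 edit neighborhood over
    the given alphabet, which is equivalent to (but vastly cheaper than)
    filtering all strings by :func:`edit_distance`.  ``cap`` guards against
    combinatorial blow-up at larger distances.

    Raises
    ------
    ValueError
        If ``max_distance`` is negative, the alphabet is empty, or the
        variant set would exceed ``cap`` strings.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    alphabet = tuple(dict.fromkeys(alphabet))
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    current = {term}
    for _ in range(max_distance):
        expanded: set[str] = set()
        for s in current:
            expanded |= _neighbors(s, alphabet)
            if len(expanded) > cap:
                raise ValueError(
                    f"variant set exceeds cap of {cap} strings; "
                    "lower max_distance or raise cap"
                )
        current = expanded
    return current


@dataclass(frozen=True)
class ScreeningCriteria:
    """The study's inclusion rules, bundled for config round-tripping.

    ``match_mode`` selects how lexical matching works:

    - ``substring_list`` (default): a record matches if any explicit variant
      occurs case-insensitively as a substring of its text.  This mirrors the
      stated criterion that a free-text field "contains" a keyword, at the
      cost of a known false-positive surface (e.g. "last" inside "blast").
    - ``generative_token``: a record matches if any whitespace/punctuation-
      delimited token of its text is within ``max_distance`` of the seed
      term — stricter, and independent of the explicit list.
    """

    seed_term: str = SEED_TERM
    max_distance: int = 1
    explicit_variants: tuple[str, ...] = TERM_VARIANTS
    cessation_keywords: tuple[str, ...] = CESSATION_KEYWORDS
    context_subreddits: frozenset[str] = frozenset({"sublocade"})
    window_start: dt.date = dt.date(2018, 3, 1)
    window_end: dt.date = dt.date(2022, 8, 31)
    match_mode: str = "substring_list"

    def __post_init__(self) -> None:
        if self.match_mode not in ("substring_list", "generative_token"):
            raise ValueError(f"unknown match_mode: {self.match_mode!r}")
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        if not self.explicit_variants or not self.cessation_keywords:
            raise ValueError("keyword lists must be non-empty")
        for v in self.explicit_variants:
            d = edit_distance(self.seed_term, v, case_insensitive=True)
            if d > self.max_distance:
                raise ValueError(
                    f"variant {v!r} is at distance {d} from "
                    f"{self.seed_term!r} (max {self.max_distance})"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningCriteria":
        kw = dict(d)
        if "explicit_variants" in kw:
            kw["explicit_variants"] = tuple(kw["explicit_variants"])
        if "cessation_keywords" in kw:
            kw["cessation_keywords"] = tuple(kw["cessation_keywords"])
        if "context_subreddits" in kw:
            kw["context_subreddits"] = frozenset(
                s.lower() for s in kw["context_subreddits"]
            )
        for key in ("window_start", "window_end"):
            if key in kw and isinstance(kw[key], str):
                kw[key] = dt.date.fromisoformat(kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "seed_term": self.seed_term,
            "max_distance": self.max_distance,
            "explicit_variants": list(self.explicit_variants),
            "cessation_keywords": list(self.cessation_keywords),
            "context_subreddits": sorted(self.context_subreddits),
            "window_start": self.window_start.isoformat(),
            "window_end": self.window_end.isoformat(),
            "match_mode": self.match_mode,
        }


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a keyword gate: which keywords matched, and where."""

    matched: bool
    matched_strings: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        assert self.matched == bool(self.matched_strings)


_TOKEN_RE = re.compile(r"[a-z0-9']+")


def _substring_matches(
    text: str, keywords: Sequence[str]
) -> tuple[tuple[str, int], ...]:
    low = text.lower()
    hits: list[tuple[str, int]] = []
    for kw in keywords:
        k = kw.lower()
        start = low.find(k)
        while start != -1:
            hits.append((kw, start))
            start = low.find(k, start + 1)
    hits.sort(key=lambda h: (h[1], h[0]))
    return tuple(hits)


def match_term(text: str, criteria: ScreeningCriteria) -> MatchResult:
    """Does the text refer to the target product lexically?"""
    if criteria.match_mode == "substring_list":
        hits = _substring_matches(text, criteria.explicit_variants)
        return MatchResult(bool(hits), hits)
    # generative_token: compare each token to the seed term
    hits = []
    low = text.lower()
    for m in _TOKEN_RE.finditer(low):
        if (
            edit_distance(m.group(), criteria.seed_term.lower())
            <= criteria.max_distance
        ):
            hits.append((m.group(), m.start()))
    return MatchResult(bool(hits), tuple(hits))


def match_context(record: NormalizedRecord, criteria: ScreeningCriteria) -> bool:
    """Was the record posted inside a context subreddit?"""
    return record.subreddit.lower() in criteria.context_subreddits


def match_cessation(
    text: str, criteria: ScreeningCriteria, token_mode: bool = False
) -> MatchResult:
    """Does the text contain a treatment-cessation keyword?

    ``token_mode=True`` requires a whole-token match (stricter than the
    default substring criterion).
    """
    if not token_mode:
        hits = _substring_matches(text, criteria.cessation_keywords)
        return MatchResult(bool(hits), hits)
    kws = {k.lower() for k in criteria.cessation_keywords}
    hits = [
        (m.group(), m.start())
        for m in _TOKEN_RE.finditer(text.lower())
        if m.group() in kws
    ]
    return MatchResult(bool(hits), tuple(hits))


def within_window(created_date: dt.date, criteria: ScreeningCriteria) -> bool:
    """Inclusive date-window test."""
    return criteria.window_start <= created_date <= criteria.window_end


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class ScreenedCorpus:
    """Retained records plus the per-stage attrition bookkeeping."""

    records: list[NormalizedRecord]
    stage_counts: list[StageCount]
    stage_survivors: dict[str, list[str]] = field(default_factory=dict)

    def attrition_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": c.stage,
                    "n_in": c.n_in,
                    "n_out": c.n_out,
                    "n_removed": c.n_removed,
                }
                for c in self.stage_counts
            ]
        )


STAGES = ("referent", "deduplicate", "cessation", "date_window")


def screen_corpus(
    records: Sequence[NormalizedRecord],
    criteria: ScreeningCriteria,
    cessation_token_mode: bool = False,
) -> ScreenedCorpus:
    """Apply the four inclusion stages in their fixed order.

    1. *referent*: keep records matching the term keywords OR posted in a
       context subreddit (parallel criteria; both labels recorded when both
       hold).
    2. *deduplicate*: keep the first occurrence of each record_id.
    3. *cessation*: keep records containing a cessation keyword.
    4. *date_window*: keep records created inside the study window.

    Retained records carry their qualifying rule labels in
    ``match_criteria``.
    """
    counts: list[StageCount] = []
    survivors: dict[str, list[str]] = {}

    stage1: list[NormalizedRecord] = []
    for rec in records:
        labels = set()
        if match_term(rec.text, criteria).matched:
            labels.add(TERM_KEYWORD)
        if match_context(rec, criteria):
            labels.add(SUBREDDIT_CONTEXT)
        if labels:
            stage1.append(rec.with_criteria(rec.match_criteria | labels))
    counts.append(StageCount("referent", len(records), len(stage1)))
    survivors["referent"] = [r.record_id for r in stage1]

    seen: set[str] = set()
    stage2: list[NormalizedRecord] = []
    for rec in stage1:
        if rec.record_id not in seen:
            seen.add(rec.record_id)
            stage2.append(rec)
    counts.append(StageCount("deduplicate", len(stage1), len(stage2)))
    survivors["deduplicate"] = [r.record_id for r in stage2]

    stage3: list[NormalizedRecord] = []
    for rec in stage2:
        if match_cessation(rec.text, criteria, token_mode=cessation_token_mode).matched:
            stage3.append(rec.with_criteria(rec.match_criteria | {CESSATION_KEYWORD}))
    counts.append(StageCount("cessation", len(stage2), len(stage3)))
    survivors["cessation"] = [r.record_id for r in stage3]

    stage4 = [r for r in stage3 if within_window(r.created_date, criteria)]
    counts.append(StageCount("date_window", len(stage3), len(stage4)))
    survivors["date_window"] = [r.record_id for r in stage4]

    return ScreenedCorpus(stage4, counts, survivors)
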