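"""Synthetic Reddit-like corpora with planted, fully-known ground truth.

The historical archive the study design assumes is no longer publicly
retrievable, so every pipeline stage is exercised against generated
corpora instead.  The generator emulates the statistical structure a
product-focused Reddit corpus exhibits:

- a dominant target subreddit (default 97.6% of records),
- heavily skewed records-per-account counts (rounded lognormal,
  moment-matched to mean 4.5 / SD 13.6 before truncation, floored at 1 and
  capped at 275),
- planted brand-name mentions — exact, or a distance-1 misspelling from the
  screening list — plus distance-2 decoy strings that must NOT match,
- cessation keywords planted either in a genuine cessation context or in an
  unrelated sense (e.g. "the finale of that show", "feeling quite hopeful"),
  reproducing the known false-positive surface of substring matching,
- epoch timestamps spanning the study window with a configurable
  out-of-window fraction, injected exact-copy duplicates, and planted PII.

Text is template-based: the pipeline under test performs lexical matching,
so templates only need controlled keyword placement, and the base
vocabulary is audited (at import time) to be free of every screening
keyword and brand-name variant.

Alongside the raw records the generator emits a :class:`GroundTruth`
(per-record lexical and construct flags) and gold codebook annotations for
every record that truly satisfies the inclusion criteria, drawn at the
study's observed construct prevalences.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .codebook import Annotation
from .corpus_io import RawRecord
from .screening import (
    CESSATION_KEYWORDS,
    SEED_TERM,
    TERM_VARIANTS,
    ScreenedCorpus,
    edit_distance,
)

__all__ = [
    "SyntheticSpec",
    "RecordTruth",
    "GroundTruth",
    "StageMetrics",
    "generate_corpus",
    "evaluate_recovery",
]

# ---------------------------------------------------------------------------
# Templates.  Base sentences must not contain any screening keyword or
# brand-name variant as a (case-insensitive) substring; this is asserted
# below at import time so template edits cannot silently break ground truth.

_BASE_SENTENCES = (
    "My next injection is in two weeks and I feel steady.",
    "Anyone have advice about insurance coverage for the shot?",
    "The clinic moved my appointment to Thursday.",
    "Week three and the nausea is mostly gone.",
    "Thanks everyone for the support, this community helps so much.",
    "My doctor said the injection site soreness fades in a few days.",
    "Does anyone get headaches in the first week after the shot?",
    "Sleep has been rough but my mood is evening out.",
)

_TERM_SENTENCES = (
    "I got my {term} shot two months ago.",
    "Been on {term} since spring and doing okay.",
    "My doctor switched me to {term} from the films.",
    "Curious how others felt during month one of {term}.",
)

# Genuine cessation context, keyed by the keyword each sentence plants.
_CESSATION_SENTENCES = {
    "taper": "I am planning to taper off next month.",
    "stop": "Thinking hard about when to stop treatment.",
    "final": "My final shot is scheduled for the 12th.",
    "quit": "I feel ready to quit for good this time.",
    "last": "I got my last injection back in June.",
    "reduce": "I want to reduce the dose before ending things.",
    "decrease": "Hoping to decrease gradually with my doctor.",
    "discontinue": "We talked about how to discontinue safely.",
}

# The same keywords in non-cessation senses: lexical hits, construct misses.
_NONCONSTRUCT_SENTENCES = {
    "taper": "The candles tapered down to nothing by midnight.",
    "stop": "The bus stop near the clinic moved across the street.",
    "final": "The finale of that show was absolutely wild.",
    "quit": "Feeling quite hopeful about things these days.",
    "last": "At long last the weather turned warm here.",
    "reduce": "Trying to reduce my screen time in the evenings.",
    "decrease": "I noticed a decrease in traffic on this road lately.",
    "discontinue": "They discontinued my favorite snack flavor, tragic.",
}

_DECOY_SENTENCE = "I keep seeing {decoy} mentioned around here."

#: Strings at Levenshtein distance exactly 2 from the seed term; these must
#: never be caught by distance-1 screening.
DECOY_STRINGS = ("sublotide", "sublacode", "zublocude", "subloxyde")

_OFF_TARGET_SUBREDDITS = (
    "opiates",
    "suboxone",
    "OpiatesRecovery",
    "Methadone",
    "addiction",
    "recovery",
    "Drugs",
    "NarcoticsAnonymous",
)


def _audit_templates() -> None:
    banned = [v.lower() for v in TERM_VARIANTS] + [k.lower() for k in CESSATION_KEYWORDS]
    clean_pool = list(_BASE_SENTENCES) + [
        t.format(term="X") for t in _TERM_SENTENCES
    ]
    for sentence in clean_pool:
        low = sentence.lower()
        for b in banned:
            assert b not in low, f"template {sentence!r} contains banned {b!r}"
    for kw, sentence in list(_CESSATION_SENTENCES.items()) + list(
        _NONCONSTRUCT_SENTENCES.items()
    ):
        low = sentence.lower()
        assert kw in low, f"{sentence!r} must contain its keyword {kw!r}"
        for v in TERM_VARIANTS:
            assert v not in low
    for d in DECOY_STRINGS:
        assert edit_distance(SEED_TERM, d) == 2, d
        for v in TERM_VARIANTS:
            assert v not in d and d not in v


_audit_templates()


# ---------------------------------------------------------------------------


class SyntheticSpec(BaseModel):
    """Parameters of one synthetic corpus; the defaults are the observed
    study conditions (construct prevalences, subreddit concentration,
    per-account activity moments, study date window)."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    n_authors: int = 1100
    rpa_mean: float = 4.5
    rpa_sd: float = 13.6
    rpa_max: int = 275
    p_target_subreddit: float = 0.976
    p_term_mention: float = 0.95
    p_exact_term: float = 0.8  # exact spelling vs a sampled misspelling
    p_decoy: float = 0.05
    p_cessation_keyword: float = 0.55
    p_cessation_construct: float = 0.438
    p_withdrawal_given_cessation: float = 0.087
    p_retrospective_given_cessation: float = 0.828
    p_intentional_given_cessation: float = 0.75
    p_sublocade_confirmed: float = 0.974
    p_craving_given_cessation: float = 1.0 / 1179.0
    p_course_given_cessation: float = 136.0 / 1179.0
    p_final_only_given_cessation: float = 24.0 / 1179.0
    p_count_only_given_cessation: float = 0.3
    p_final_dose_100: float = 0.794
    p_submission: float = 0.3
    p_out_of_window: float = 0.05
    p_pii: float = 0.03
    n_duplicates: int = 25
    window_start: dt.date = dt.date(2018, 3, 1)
    window_end: dt.date = dt.date(2022, 8, 31)
    keywords_only_genuine: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        for name, val in self.model_dump().items():
            if name.startswith("p_") and not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.rpa_max < self.rpa_mean:
            raise ValueError("rpa_max must be >= rpa_mean")
        if self.n_authors < 1:
            raise ValueError("n_authors must be positive")
        if self.window_start > self.window_end:
            raise ValueError("window_start must be <= window_end")
        return self

    @classmethod
    def clean(cls, seed: int, **overrides) -> "SyntheticSpec":
        """A corpus with no decoys, no PII, and cessation keywords planted
        only in genuine cessation contexts — every lexical gate should then
        recover the planted truth perfectly."""
        base = dict(
            seed=seed,
            p_decoy=0.0,
            p_pii=0.0,
            keywords_only_genuine=True,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RecordTruth:
    """Planted per-record facts, consistent with the text by construction."""

    record_id: str
    author: str
    subreddit: str
    target_subreddit: bool
    in_window: bool
    has_term_mention: bool
    mention_string: Optional[str]
    has_decoy: bool
    has_cessation_keyword: bool
    cessation_keyword: Optional[str]
    true_cessation_context: bool
    is_duplicate_of: Optional[str]
    planted_pii: list[str] = field(default_factory=list)

    @property
    def eligible_referent(self) -> bool:
        return self.has_term_mention or self.target_subreddit

    @property
    def passes_all_gates(self) -> bool:
        return (
            self.eligible_referent
            and self.has_cessation_keyword
            and self.in_window
            and self.is_duplicate_of is None
        )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


@dataclass
class GroundTruth:
    """Everything the generator planted, for stage-wise recovery checks."""

    records: list[RecordTruth]
    per_author_counts: dict[str, int]
    params: dict

    @property
    def by_id(self) -> dict[str, RecordTruth]:
        out: dict[str, RecordTruth] = {}
        for r in self.records:
            out.setdefault(r.record_id, r)
        return out

    @property
    def pii_inventory(self) -> list[tuple[str, str]]:
        return [(r.record_id, s) for r in self.records for s in r.planted_pii]

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": [r.to_dict() for r in self.records],
                "per_author_counts": self.per_author_counts,
                "params": self.params,
            },
            ensure_ascii=False,
            indent=None,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            records=[RecordTruth(**r) for r in obj["records"]],
            per_author_counts=obj["per_author_counts"],
            params=obj["params"],
        )


def _base36(n: int) -> str:
    digits = "0123456789abcdefghijklmnopqrstuvwxyz"
    if n == 0:
        return "0"
    out = []
    while n:
        n, r = divmod(n, 36)
        out.append(digits[r])
    return "".join(reversed(out))


def _author_counts(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    cv2 = (spec.rpa_sd / spec.rpa_mean) ** 2
    sigma = float(np.sqrt(np.log1p(cv2)))
    mu = float(np.log(spec.rpa_mean) - sigma**2 / 2)
    raw = rng.lognormal(mu, sigma, size=spec.n_authors)
    return np.clip(np.round(raw), 1, spec.rpa_max).astype(int)


_EPOCH = dt.datetime(1970, 1, 1, tzinfo=dt.timezone.utc)


def _date_to_epoch(d: dt.date) -> int:
    return int(
        (dt.datetime(d.year, d.month, d.day, tzinfo=dt.timezone.utc) - _EPOCH).total_seconds()
    )


def _draw_timestamp(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[int, bool]:
    start = _date_to_epoch(spec.window_start)
    end = _date_to_epoch(spec.window_end) + 86_399  # inclusive last day
    if rng.random() < spec.p_out_of_window:
        if rng.random() < 0.5:
            lo = max(0, start - 270 * 86_400)
            return int(rng.integers(lo, start)), False
        return int(rng.integers(end + 1, end + 106 * 86_400)), False
    return int(rng.integers(start, end + 1)), True


def _make_pii(rng: np.random.Generator, i: int) -> str:
    kind = rng.integers(4)
    if kind == 0:
        return f"throwaway{i}@example.com"
    if kind == 1:
        return f"555-{rng.integers(100, 1000)}-{rng.integers(1000, 10000)}"
    if kind == 2:
        return f"https://example.com/thread/{i}"
    return f"u/helpful_user{i}"


def _pii_sentence(pii: str) -> str:
    if "@" in pii:
        return f"Message me at {pii} if you want details."
    if pii.startswith("http"):
        return f"There is more info at {pii} for anyone curious."
    if pii.startswith("u/"):
        return f"Ask {pii} about their experience."
    return f"You can call me at {pii} anytime."


def _gold_annotation(
    truth: RecordTruth, spec: SyntheticSpec, rng: np.random.Generator
) -> Annotation:
    """Code one screened record the way the study's coder would."""
    a = dict(record_id=truth.record_id)
    referent_real = truth.has_term_mention or truth.target_subreddit
    sublocade = int(referent_real and rng.random() < spec.p_sublocade_confirmed)
    a["sublocade"] = sublocade
    # construct truth is decided at text-planting time (a genuine cessation
    # sentence was embedded with probability p_cessation_construct given a
    # keyword), so coding it is deterministic here
    cessation = int(sublocade == 1 and truth.true_cessation_context)
    a["any_cessation"] = cessation
    if cessation:
        if rng.random() < spec.p_intentional_given_cessation:
            a["intentional_cessation"] = 1
        else:
            a["circumstantial_cessation"] = 1
        a["cessation_timing"] = (
            "retrospective"
            if rng.random() < spec.p_retrospective_given_cessation
            else "planned"
        )
        if rng.random() < spec.p_withdrawal_given_cessation:
            if rng.random() < 0.7:
                a["postcourse_withdrawal"] = 1
            else:
                a["within_course_withdrawal"] = 1
        if rng.random() < spec.p_craving_given_cessation:
            a["opioid_craving"] = 1

        # treatment-course detail: full sequence, final dose only, or count only
        u = rng.random()
        final_dose = 100 if rng.random() < spec.p_final_dose_100 else 300
        n_doses = 1 + int(
            min(rng.negative_binomial(1.6636, 0.35672), 19)
        )  # mean 4, SD 2.9, median 3 before capping
        if u < spec.p_course_given_cessation:
            if n_doses == 1:
                course = [final_dose]
            elif final_dose == 300:
                course = [300] * n_doses
            else:
                n_300 = int(rng.integers(1, n_doses))
                course = [300] * n_300 + [100] * (n_doses - n_300)
            a["course_of_treatment"] = course
            a["number_of_doses"] = len(course)
            a["final_dosage"] = course[-1]
        elif u < spec.p_course_given_cessation + spec.p_final_only_given_cessation:
            a["final_dosage"] = final_dose
        elif (
            u
            < spec.p_course_given_cessation
            + spec.p_final_only_given_cessation
            + spec.p_count_only_given_cessation
        ):
            a["number_of_doses"] = n_doses
        if rng.random() < 0.3:
            ds = int(rng.integers(1, 13))
            db = ds + int(rng.integers(0, 25))
            a["duration_sublocade"] = ds
            a["duration_buprenorphine"] = db
            a["duration_moud"] = db + int(rng.integers(0, 13))
        if rng.random() < 0.15:
            a["prior_moud"] = "transmucosal buprenorphine"
        if rng.random() < 0.015:
            a["subsequent_moud"] = str(
                rng.choice(["naltrexone", "transmucosal buprenorphine", "sublocade"])
            )
    return Annotation(**a)


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[RawRecord], GroundTruth, list[Annotation]]:
    """Generate records, ground truth and gold annotations.

    Deterministic for a fixed seed (byte-identical output).  Duplicates are
    exact copies (same record id) of referent-eligible records, appended
    after the originals so first-occurrence deduplication keeps the
    original.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _author_counts(spec, rng)
    records: list[RawRecord] = []
    truths: list[RecordTruth] = []
    idx = 0
    for a_i, k in enumerate(counts):
        author = f"author_{a_i:05d}"
        for _ in range(int(k)):
            rid = "r" + _base36(1_000_000 + idx)
            idx += 1
            target = rng.random() < spec.p_target_subreddit
            if target:
                subreddit = "Sublocade"
            else:
                subreddit = str(_OFF_TARGET_SUBREDDITS[rng.integers(len(_OFF_TARGET_SUBREDDITS))])
            ts, in_window = _draw_timestamp(spec, rng)

            sentences = [str(_BASE_SENTENCES[rng.integers(len(_BASE_SENTENCES))])]
            mention = None
            if rng.random() < spec.p_term_mention:
                if rng.random() < spec.p_exact_term:
                    mention = SEED_TERM
                else:
                    mention = str(TERM_VARIANTS[1 + rng.integers(len(TERM_VARIANTS) - 1)])
                tmpl = str(_TERM_SENTENCES[rng.integers(len(_TERM_SENTENCES))])
                sentences.append(tmpl.format(term=mention))
            has_decoy = rng.random() < spec.p_decoy
            if has_decoy:
                decoy = str(DECOY_STRINGS[rng.integers(len(DECOY_STRINGS))])
                sentences.append(_DECOY_SENTENCE.format(decoy=decoy))
            kw = None
            true_context = False
            if rng.random() < spec.p_cessation_keyword:
                kw = str(CESSATION_KEYWORDS[rng.integers(len(CESSATION_KEYWORDS))])
                true_context = (
                    spec.keywords_only_genuine
                    or rng.random() < spec.p_cessation_construct
                )
                # genuine context gets a real cessation sentence; otherwise
                # the keyword appears in an unrelated sense
                if true_context:
                    sentences.append(_CESSATION_SENTENCES[kw])
                else:
                    sentences.append(_NONCONSTRUCT_SENTENCES[kw])
            pii: list[str] = []
            if rng.random() < spec.p_pii:
                s = _make_pii(rng, idx)
                pii.append(s)
                sentences.append(_pii_sentence(s))

            order = rng.permutation(len(sentences))
            sentences = [sentences[i] for i in order]
            if rng.random() < spec.p_submission:
                rec = RawRecord(
                    id=rid,
                    author=author,
                    created_utc=ts,
                    subreddit=subreddit,
                    kind="submission",
                    title=sentences[0],
                    selftext=" ".join(sentences[1:]),
                )
            else:
                rec = RawRecord(
                    id=rid,
                    author=author,
                    created_utc=ts,
                    subreddit=subreddit,
                    kind="comment",
                    body=" ".join(sentences),
                )
            records.append(rec)
            truths.append(
                RecordTruth(
                    record_id=rid,
                    author=author,
                    subreddit=subreddit,
                    target_subreddit=target,
                    in_window=in_window,
                    has_term_mention=mention is not None,
                    mention_string=mention,
                    has_decoy=has_decoy,
                    has_cessation_keyword=kw is not None,
                    cessation_keyword=kw,
                    true_cessation_context=true_context,
                    is_duplicate_of=None,
                    planted_pii=pii,
                )
            )

    # inject exact-copy duplicates of referent-eligible records
    eligible_idx = [i for i, t in enumerate(truths) if t.eligible_referent]
    n_dup = min(spec.n_duplicates, len(eligible_idx))
    if n_dup:
        chosen = rng.choice(len(eligible_idx), size=n_dup, replace=False)
        for ci in sorted(int(c) for c in chosen):
            i = eligible_idx[ci]
            records.append(records[i])
            src = truths[i]
            dup = RecordTruth(**{**src.__dict__, "is_duplicate_of": src.record_id})
            dup.planted_pii = list(src.planted_pii)
            truths.append(dup)

    gold = [
        _gold_annotation(t, spec, rng) for t in truths if t.passes_all_gates
    ]
    truth = GroundTruth(
        records=truths,
        per_author_counts={
            f"author_{i:05d}": int(c) for i, c in enumerate(counts)
        },
        params=spec.model_dump(mode="json"),
    )
    return records, truth, gold


# ---------------------------------------------------------------------------


@dataclass
class StageMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 1.0 if (self.tp + self.fp) == 0 else self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        return 1.0 if (self.tp + self.fn) == 0 else self.tp / (self.tp + self.fn)


def evaluate_recovery(
    screened: ScreenedCorpus,
    truth: GroundTruth,
    id_mapper: Callable[[str], str] | None = None,
) -> dict[str, StageMetrics]:
    """Stage-wise precision/recall of screening against planted truth.

    ``id_mapper`` maps raw generator record ids to the ids the screened
    corpus carries (e.g. the obfuscator used during normalization).

    - *referent*: lexical truth — a record mentions the term or sits in the
      target subreddit.  Substring screening recovers this exactly.
    - *cessation*: construct truth — the keyword was planted in a genuine
      cessation context.  Non-construct keyword plants surface here as
      false positives of the lexical gate.
    - *date_window*: timestamp truth.
    """
    mapper = id_mapper if id_mapper is not None else (lambda s: s)
    by_id = {mapper(rid): t for rid, t in truth.by_id.items()}

    def metrics(predicted: set[str], candidates: set[str], want) -> StageMetrics:
        unknown = predicted - set(by_id)
        if unknown:
            raise ValueError(
                f"{len(unknown)} screened id(s) not present in ground truth"
            )
        pos = {rid for rid in candidates if want(by_id[rid])}
        tp = len(predicted & pos)
        return StageMetrics(tp=tp, fp=len(predicted - pos), fn=len(pos - predicted))

    all_ids = set(by_id)
    referent_pred = set(screened.stage_survivors["referent"])
    dedup_pred = set(screened.stage_survivors["deduplicate"])
    cess_pred = set(screened.stage_survivors["cessation"])
    window_pred = set(screened.stage_survivors["date_window"])

    return {
        "referent": metrics(referent_pred, all_ids, lambda t: t.eligible_referent),
        "cessation": metrics(
            cess_pred, dedup_pred, lambda t: t.true_cessation_context
        ),
        "date_window": metrics(window_pred, cess_pred, lambda t: t.in_window),
    }
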