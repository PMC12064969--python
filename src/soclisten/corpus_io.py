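"""Ingestion and normalization of Reddit-style records.

Input is JSON Lines in the Pushshift dialect: one object per line carrying
``id``, ``author``, ``created_utc`` (epoch seconds), ``subreddit`` and
either ``body`` (comments) or ``title``/``selftext`` (submissions).
Normalization assembles a single text field per record, lowercases the
subreddit, converts the epoch timestamp to a UTC calendar date and, when an
obfuscator is supplied, replaces the platform identifiers with one-way
tokens.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecord",
    "NormalizedRecord",
    "EmptyCorpusError",
    "read_records",
    "normalize",
    "write_records",
    "read_normalized",
    "write_normalized",
    "normalized_to_frame",
]


class EmptyCorpusError(ValueError):
    """Raised when an input file yields no parseable records."""


@dataclass(frozen=True)
class RawRecord:
    """One Reddit submission or comment as ingested.

    Comments carry ``body``; submissions carry ``title`` and/or
    ``selftext``.  ``created_utc`` counts seconds since the Unix epoch.
    """

    id: str
    author: str
    created_utc: int
    subreddit: str
    kind: Literal["submission", "comment"]
    title: str | None = None
    selftext: str | None = None
    body: str | None = None

    def __post_init__(self) -> None:
        if self.created_utc < 0:
            raise ValueError("created_utc must be >= 0")
        if self.kind == "comment":
            if self.title is not None or self.selftext is not None:
                raise ValueError("comments carry body only")
        elif self.kind == "submission":
            if self.body is not None:
                raise ValueError("submissions carry title/selftext only")
        else:
            raise ValueError(f"unknown kind: {self.kind!r}")

    def to_pushshift(self) -> dict:
        d = {
            "id": self.id,
            "author": self.author,
            "created_utc": self.created_utc,
            "subreddit": self.subreddit,
        }
        if self.kind == "comment":
            d["body"] = self.body or ""
        else:
            if self.title is not None:
                d["title"] = self.title
            if self.selftext is not None:
                d["selftext"] = self.selftext
        return d


@dataclass(frozen=True)
class NormalizedRecord:
    """Unified record: one text field, tokenized IDs, match provenance."""

    record_id: str
    author_id: str
    created_date: dt.date
    subreddit: str
    text: str
    kind: str
    match_criteria: frozenset[str] = frozenset()
    empty_text: bool = False

    def with_criteria(self, criteria: Iterable[str]) -> "NormalizedRecord":
        return replace(self, match_criteria=frozenset(criteria))

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "author_id": self.author_id,
            "created_date": self.created_date.isoformat(),
            "subreddit": self.subreddit,
            "text": self.text,
            "kind": self.kind,
            "match_criteria": sorted(self.match_criteria),
            "empty_text": self.empty_text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizedRecord":
        return cls(
            record_id=d["record_id"],
            author_id=d["author_id"],
            created_date=dt.date.fromisoformat(d["created_date"]),
            subreddit=d["subreddit"],
            text=d["text"],
            kind=d["kind"],
            match_criteria=frozenset(d.get("match_criteria", ())),
            empty_text=bool(d.get("empty_text", False)),
        )


def _raw_from_obj(obj: dict) -> RawRecord:
    kind = "comment" if "body" in obj else "submission"
    common = dict(
        id=str(obj["id"]),
        author=str(obj.get("author", "[deleted]")),
        created_utc=int(obj["created_utc"]),
        subreddit=str(obj.get("subreddit", "")),
        kind=kind,
    )
    if kind == "comment":
        return RawRecord(body=str(obj["body"]), **common)
    title = obj.get("title")
    selftext = obj.get("selftext")
    return RawRecord(
        title=None if title is None else str(title),
        selftext=None if selftext is None else str(selftext),
        **common,
    )


def read_records(
    path: str | Path, dialect: str = "pushshift_jsonl"
) -> list[RawRecord]:
    """Read raw records from a JSON Lines file.

    Malformed lines (bad JSON, missing required fields) are skipped and
    counted, not fatal; lines whose JSON object carries a ``_provenance``
    key are treated as artifact headers and ignored.  A file with zero
    parseable records raises :class:`EmptyCorpusError`.
    """
    if dialect != "pushshift_jsonl":
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    records: list[RawRecord] = []
    n_bad = 0
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            n_lines += 1
            try:
                obj = json.loads(line)
                if isinstance(obj, dict) and "_provenance" in obj:
                    n_lines -= 1
                    continue
                records.append(_raw_from_obj(obj))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                n_bad += 1
    if n_bad:
        logger.warning("skipped %d malformed line(s) in %s", n_bad, path)
    if n_lines and not records:
        raise EmptyCorpusError(f"no parseable records in {path}")
    if not n_lines:
        raise EmptyCorpusError(f"{path} is empty")
    return records


def write_records(records: Sequence[RawRecord], path: str | Path) -> None:
    """Write raw records back out as Pushshift-dialect JSON Lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_pushshift(), ensure_ascii=False) + "\n")


def normalize(
    raw: RawRecord,
    obfuscator: Callable[[str], str] | None = None,
    redactor: Callable[[str], str] | None = None,
) -> NormalizedRecord:
    """Turn a raw record into the unified analysis representation.

    Comment text is the body verbatim; submission text is title and
    selftext joined by a single newline (a missing part contributes an
    empty string, so substring matches never span the two fields).  The
    calendar date is taken in UTC — the only timezone under which the
    study's date boundaries are reproducible.  A record with no text at
    all is flagged ``empty_text`` rather than rejected.
    """
    if raw.kind == "comment":
        text = raw.body or ""
    else:
        parts = [raw.title or "", raw.selftext or ""]
        text = "\n".join(parts) if any(parts) else ""
        text = text.strip("\n")
    if redactor is not None:
        text = redactor(text)
    ident = obfuscator if obfuscator is not None else (lambda v: v)
    created = dt.datetime.fromtimestamp(raw.created_utc, tz=dt.timezone.utc).date()
    return NormalizedRecord(
        record_id=ident(raw.id),
        author_id=ident(raw.author),
        created_date=created,
        subreddit=raw.subreddit.lower(),
        text=text,
        kind=raw.kind,
        empty_text=not text,
    )


def write_normalized(
    records: Sequence[NormalizedRecord],
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if provenance is not None:
            fh.write(json.dumps({"_provenance": provenance}) + "\n")
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")


def read_normalized(path: str | Path) -> list[NormalizedRecord]:
    path = Path(path)
    out: list[NormalizedRecord] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "_provenance" in obj:
                continue
            out.append(NormalizedRecord.from_dict(obj))
    return out


def normalized_to_frame(records: Sequence[NormalizedRecord]) -> pd.DataFrame:
    """Tabular view (CSV-exportable) with the same columns as the JSONL."""
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(
        rows,
        columns=[
            "record_id",
            "author_id",
            "created_date",
            "subreddit",
            "text",
            "kind",
            "match_criteria",
            "empty_text",
        ],
    )
    if len(df):
        df["match_criteria"] = df["match_criteria"].map(";".join)
    return df
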