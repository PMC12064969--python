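"""The manual-coding codebook: schema, validation and record joining.

Each sampled record is hand-coded against a fixed schema: binary construct
flags (product referent, cessation, withdrawal during and after the course,
opioid craving), treatment details (final dose in mg of buprenorphine, dose
sequence, number of doses, treatment durations in months) and free-text
fields for concurrent or subsequent medications and nonmedical opioid use.
This module represents one coded row, checks the logical consistency rules
that the construct definitions imply, and joins annotation tables back to
the screened corpus.

Validation never raises on bad data: violations are themselves data,
collected into a :class:`ValidationReport` with a severity per rule —
logical contradictions are errors, clinically implausible values are
warnings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .corpus_io import NormalizedRecord

__all__ = [
    "Annotation",
    "Violation",
    "ValidationReport",
    "TABLE1_FIELDS",
    "ANNOTATION_COLUMNS",
    "MAX_DOSE_MG",
    "MARKETED_DOSES_MG",
    "parse_course",
    "format_course",
    "validate_annotation",
    "validate_annotations",
    "join_annotations",
    "annotations_to_frame",
    "annotations_from_frame",
    "read_annotations_csv",
    "write_annotations_csv",
]

#: Marketed maintenance doses; other positive values <= the cap are treated
#: as partial doses (providers do administer partial doses off-label).
MARKETED_DOSES_MG = (100, 300)
MAX_DOSE_MG = 300

#: Codebook field names as published, mapped to their snake_case homes.
#: Record-level fields live on NormalizedRecord; coded fields on Annotation.
TABLE1_FIELDS: dict[str, tuple[str, str]] = {
    "ID": ("record", "record_id"),
    "Text": ("record", "text"),
    "Author ID": ("record", "author_id"),
    "Created date": ("record", "created_date"),
    "Notes": ("annotation", "notes"),
    "Sublocade": ("annotation", "sublocade"),
    "Any cessation": ("annotation", "any_cessation"),
    "Match criteria": ("record", "match_criteria"),
    "Intentional cessation": ("annotation", "intentional_cessation"),
    "Circumstantial cessation": ("annotation", "circumstantial_cessation"),
    "Within-course withdrawal": ("annotation", "within_course_withdrawal"),
    "Postcourse withdrawal": ("annotation", "postcourse_withdrawal"),
    "Final dosage": ("annotation", "final_dosage"),
    "Opioid craving": ("annotation", "opioid_craving"),
    "Duration of MOUD treatment": ("annotation", "duration_moud"),
    "Duration of buprenorphine treatment": ("annotation", "duration_buprenorphine"),
    "Duration of Sublocade treatment": ("annotation", "duration_sublocade"),
    "Course of treatment": ("annotation", "course_of_treatment"),
    "Number of doses": ("annotation", "number_of_doses"),
    "Prior MOUD": ("annotation", "prior_moud"),
    "Subsequent MOUD": ("annotation", "subsequent_moud"),
    "Concurrent MOUD": ("annotation", "concurrent_moud"),
    "Subsequent NMOU": ("annotation", "subsequent_nmou"),
    "Concurrent NMOU": ("annotation", "concurrent_nmou"),
}

_BINARY_FIELDS = (
    "sublocade",
    "any_cessation",
    "intentional_cessation",
    "circumstantial_cessation",
    "within_course_withdrawal",
    "postcourse_withdrawal",
    "opioid_craving",
)


class Annotation(BaseModel):
    """One coded record.

    ``cessation_timing`` distinguishes retrospective accounts of a past
    cessation from statements of a planned one; the published results
    report this split, so the schema carries it even though it is coded
    alongside (not within) the binary constructs.
    """

    model_config = ConfigDict(extra="forbid")

    record_id: str
    sublocade: int = 0
    any_cessation: int = 0
    intentional_cessation: int = 0
    circumstantial_cessation: int = 0
    within_course_withdrawal: int = 0
    postcourse_withdrawal: int = 0
    opioid_craving: int = 0
    final_dosage: Optional[int] = None
    duration_moud: Optional[int] = None
    duration_buprenorphine: Optional[int] = None
    duration_sublocade: Optional[int] = None
    course_of_treatment: Optional[list[int]] = None
    number_of_doses: Optional[int] = None
    prior_moud: Optional[str] = None
    subsequent_moud: Optional[str] = None
    concurrent_moud: Optional[str] = None
    subsequent_nmou: Optional[str] = None
    concurrent_nmou: Optional[str] = None
    notes: Optional[str] = None
    cessation_timing: Optional[str] = None


ANNOTATION_COLUMNS = list(Annotation.model_fields)


@dataclass(frozen=True)
class Violation:
    rule: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    record_id: str
    violations: list[Violation]

    @property
    def valid(self) -> bool:
        return not self.violations

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]


def parse_course(text: str) -> list[int]:
    """Parse a dose-sequence string like ``"100, 300, 300, 100"``."""
    if text is None or not text.strip():
        return []
    doses = []
    for tok in text.split(","):
        tok = tok.strip()
        try:
            doses.append(int(tok))
        except ValueError:
            raise ValueError(f"non-numeric dose token: {tok!r}") from None
    return doses


def format_course(course: Sequence[int] | None) -> str:
    return "" if not course else ", ".join(str(d) for d in course)


def validate_annotation(a: Annotation) -> ValidationReport:
    """Check one coded row against the codebook's consistency rules."""
    v: list[Violation] = []

    def err(rule: str, msg: str) -> None:
        v.append(Violation(rule, "error", msg))

    def warn(rule: str, msg: str) -> None:
        v.append(Violation(rule, "warning", msg))

    for name in _BINARY_FIELDS:
        val = getattr(a, name)
        if val not in (0, 1):
            err("binary_domain", f"{name}={val!r} is not 0/1")

    if (a.intentional_cessation == 1 or a.circumstantial_cessation == 1) and (
        a.any_cessation != 1
    ):
        err(
            "cessation_subtype_implies_any",
            "intentional/circumstantial cessation coded without any_cessation",
        )
    if (
        a.any_cessation == 1
        or a.within_course_withdrawal == 1
        or a.postcourse_withdrawal == 1
    ) and a.sublocade != 1:
        err(
            "construct_implies_referent",
            "cessation/withdrawal construct coded on a record not coded "
            "as a product referent",
        )
    if a.cessation_timing is not None:
        if a.cessation_timing not in ("retrospective", "planned"):
            err(
                "timing_domain",
                f"cessation_timing={a.cessation_timing!r} not in "
                "{retrospective, planned}",
            )
        elif a.any_cessation != 1:
            err("timing_requires_cessation", "cessation_timing without any_cessation")

    course = a.course_of_treatment
    if course is not None and a.number_of_doses is not None:
        if len(course) != a.number_of_doses:
            err(
                "course_length",
                f"course has {len(course)} dose(s) but number_of_doses="
                f"{a.number_of_doses}",
            )
    if a.final_dosage is not None and course:
        if a.final_dosage != course[-1]:
            err(
                "final_dose_mismatch",
                f"final_dosage={a.final_dosage} but course ends in {course[-1]}",
            )
    if a.number_of_doses is not None and a.number_of_doses < 1:
        err("dose_count_domain", f"number_of_doses={a.number_of_doses} < 1")

    all_doses = list(course or [])
    if a.final_dosage is not None:
        all_doses.append(a.final_dosage)
    for d in all_doses:
        if not (0 < d <= MAX_DOSE_MG):
            err("dose_range", f"dose {d} mg outside (0, {MAX_DOSE_MG}]")
        elif d not in MARKETED_DOSES_MG:
            warn("dose_unusual", f"dose {d} mg is not a marketed dose (partial?)")

    durations = {
        "duration_moud": a.duration_moud,
        "duration_buprenorphine": a.duration_buprenorphine,
        "duration_sublocade": a.duration_sublocade,
    }
    for name, months in durations.items():
        if months is not None and months < 0:
            err("duration_domain", f"{name}={months} < 0")
    ds, db, dm = a.duration_sublocade, a.duration_buprenorphine, a.duration_moud
    if ds is not None and db is not None and ds > db:
        err("duration_nesting", f"duration_sublocade={ds} > duration_buprenorphine={db}")
    if db is not None and dm is not None and db > dm:
        err("duration_nesting", f"duration_buprenorphine={db} > duration_moud={dm}")

    return ValidationReport(a.record_id, v)


def validate_annotations(annotations: Sequence[Annotation]) -> list[ValidationReport]:
    return [validate_annotation(a) for a in annotations]


@dataclass
class AnnotatedCorpus:
    frame: pd.DataFrame
    n_annotated: int
    n_unannotated: int
    orphan_record_ids: list[str]


def join_annotations(
    records: Sequence[NormalizedRecord], annotations: Sequence[Annotation]
) -> AnnotatedCorpus:
    """Left-join coded rows onto records by record_id.

    Records without a coded row are flagged; annotations whose record_id
    does not appear in the corpus are listed as orphans.  Two coded rows
    for one record are a hard conflict.
    """
    seen: set[str] = set()
    for a in annotations:
        if a.record_id in seen:
            raise ValueError(f"duplicate annotation for record_id {a.record_id!r}")
        seen.add(a.record_id)

    from .corpus_io import normalized_to_frame

    rec_df = normalized_to_frame(records)
    ann_df = annotations_to_frame(annotations)
    merged = rec_df.merge(ann_df, on="record_id", how="left", indicator=True)
    merged["annotated"] = (merged.pop("_merge") == "both").astype(int)
    record_ids = set(rec_df["record_id"])
    orphans = sorted(seen - record_ids)
    n_annotated = int(merged["annotated"].sum())
    return AnnotatedCorpus(
        frame=merged,
        n_annotated=n_annotated,
        n_unannotated=len(merged) - n_annotated,
        orphan_record_ids=orphans,
    )


def annotations_to_frame(annotations: Sequence[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        d = a.model_dump()
        d["course_of_treatment"] = format_course(a.course_of_treatment)
        rows.append(d)
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def annotations_from_frame(df: pd.DataFrame) -> list[Annotation]:
    out = []
    for row in df.to_dict(orient="records"):
        clean: dict = {}
        for key, val in row.items():
            if key not in Annotation.model_fields:
                continue
            if pd.isna(val) or val == "":
                clean[key] = None
            elif key == "course_of_treatment":
                clean[key] = parse_course(str(val))
            else:
                clean[key] = val.item() if hasattr(val, "item") else val
        for name in _BINARY_FIELDS:
            if clean.get(name) is None:
                clean[name] = 0
        out.append(Annotation(**clean))
    return out


def write_annotations_csv(annotations: Sequence[Annotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False)


def read_annotations_csv(path) -> list[Annotation]:
    df = pd.read_csv(path, comment="#", dtype={"record_id": str})
    # integers read as float when NaN present; coerce back
    for col in df.columns:
        if df[col].dtype.kind == "f" and col != "course_of_treatment":
            df[col] = df[col].astype("Int64")
    return annotations_from_frame(df)
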