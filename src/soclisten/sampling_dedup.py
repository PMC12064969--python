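"""Deduplication and seeded random sampling of the screened corpus.

The study design codes a simple random sample (50% by default) of the
deduplicated corpus.  Sampling here is uniform without replacement,
deterministic for a fixed seed, and order-preserving, with the sample size
fixed by half-up rounding of ``n * fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np
import pandas as pd

from ._util import round_half_up
from .corpus_io import NormalizedRecord

T = TypeVar("T")

__all__ = ["SamplePlan", "deduplicate", "sample_size", "draw_sample", "membership_table"]


@dataclass(frozen=True)
class SamplePlan:
    """Fraction, seed and rounding rule of a simple random sample."""

    fraction: float = 0.5
    seed: int = 0
    size_rule: str = "round_half_up"

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if self.size_rule != "round_half_up":
            raise ValueError(f"unknown size_rule: {self.size_rule!r}")


def deduplicate(
    records: Sequence[NormalizedRecord],
) -> tuple[list[NormalizedRecord], int]:
    """Keep the first occurrence of each record_id, preserving order.

    Returns the deduplicated sequence and the number of records removed.
    """
    seen: set[str] = set()
    kept: list[NormalizedRecord] = []
    for rec in records:
        if rec.record_id not in seen:
            seen.add(rec.record_id)
            kept.append(rec)
    return kept, len(records) - len(kept)


def sample_size(n: int, plan: SamplePlan) -> int:
    """Half-up rounded sample size: 6082 records at 50% -> 3041."""
    return int(round_half_up(n * plan.fraction))


def draw_sample(records: Sequence[T], plan: SamplePlan) -> list[T]:
    """Uniform without-replacement sample preserving input order."""
    n = len(records)
    if n == 0:
        return []
    k = sample_size(n, plan)
    rng = np.random.default_rng(plan.seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [records[i] for i in idx]


def membership_table(
    records: Sequence[NormalizedRecord], sampled: Sequence[NormalizedRecord]
) -> pd.DataFrame:
    """record_id -> sampled flag, one row per deduplicated record."""
    in_sample = {r.record_id for r in sampled}
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "sampled": [int(r.record_id in in_sample) for r in records],
        }
    )
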