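"""Subject-level QA: aggregate record flags into per-subject decisions.

A subject is flagged when the proportion of their scored measurements that
were flagged exceeds a cutoff (strictly greater — "more than 20%" means
exactly 20% is not flagged).  Records whose score is undefined (e.g.
single-measurement subjects) are excluded from both numerator and
denominator.  The summary is advisory; nothing is removed automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .longitudinal import ScoredRecord

__all__ = ["SubjectSummary", "summarize_subject", "summarize_subjects"]


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    variable: str
    n_scored: int
    n_flagged: int
    proportion: float  # NaN when n_scored == 0
    subject_flagged: bool


def summarize_subject(
    subject_id: str,
    variable: str,
    scored: Sequence[ScoredRecord],
    proportion_cutoff: float = 0.20,
) -> SubjectSummary:
    """Summarize one subject's scored records into a QA decision.

    ``subject_flagged`` iff flagged proportion > ``proportion_cutoff``
    (strict).  Records with undefined q_r (status != "scored") are ignored;
    if none remain, the proportion is NaN and the subject is not flagged.
    """
    usable = [r for r in scored if r.status == "scored" and not math.isnan(r.q_r)]
    n = len(usable)
    k = sum(r.flag_r for r in usable)
    if n == 0:
        return SubjectSummary(subject_id, variable, 0, 0, math.nan, False)
    prop = k / n
    return SubjectSummary(subject_id, variable, n, k, prop, prop > proportion_cutoff)


def summarize_subjects(
    scored_by_subject: Iterable[tuple[str, str, Sequence[ScoredRecord]]],
    proportion_cutoff: float = 0.20,
) -> list[SubjectSummary]:
    """Summaries for (subject_id, variable, scored records) triples."""
    return [
        summarize_subject(sid, var, recs, proportion_cutoff)
        for sid, var, recs in scored_by_subject
    ]
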