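"""Patient-level aggregation, positivity classification, and term selection.

The classifier's decision statistic is the number of DISTINCT lexicon terms
with at least one affirmed mention anywhere in a patient's notes — category
counting rather than raw term counts, so a patient with one frequently
documented problem (or one recurring false-positive source) does not cross
the threshold on volume alone. A patient is called positive when that count
reaches the threshold (default 9 of the 22 default terms).

Term selection compares per-patient occurrence counts of each candidate term
between an index cohort and a control cohort and retains a term only when
the two interquartile intervals are disjoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .context import FilterConfig
from .lexicon import Lexicon
from .textmatch import STATUS_AFFIRMED, Mention

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class PatientTally:
    """Distinct affirmed terms and raw affirmed occurrence counts."""

    patient_id: str
    occurrences: Mapping[str, int]  # term_id -> affirmed mention count (>= 1)

    @property
    def terms_present(self) -> frozenset:
        return frozenset(self.occurrences)

    @property
    def n_distinct(self) -> int:
        return len(self.occurrences)


@dataclass(frozen=True)
class ClassifierConfig:
    """Positivity threshold on the distinct-term count."""

    threshold: int = 9
    lexicon: Optional[Lexicon] = None
    filter_config: Optional[FilterConfig] = None

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold}")


@dataclass(frozen=True)
class CohortSummary:
    group: str
    values: tuple[int, ...]  # per-patient distinct-term counts
    mean: float
    q1: float
    q3: float
    minimum: int
    maximum: int


@dataclass(frozen=True)
class TermStats:
    term_id: str
    group: str
    counts: tuple[int, ...]  # per-patient occurrence counts (0 when absent)
    q1: float
    q3: float


def tally_patient(
    mentions: Iterable[Mention],
    lexicon: Lexicon,
    patient_id: Optional[str] = None,
) -> PatientTally:
    """Aggregate one patient's filtered mentions into a tally.

    Only affirmed mentions count; negated, templated, polysemy-excluded and
    misallocated mentions contribute nothing.
    """
    mentions = list(mentions)
    pids = {m.patient_id for m in mentions}
    if patient_id is None:
        if len(pids) != 1:
            raise ValueError(
                "patient_id required when mentions are empty or span patients"
            )
        patient_id = next(iter(pids))
    elif pids - {patient_id}:
        raise ValueError(f"mentions span multiple patients: {sorted(pids)}")
    counts: Counter = Counter()
    for m in mentions:
        if m.term_id not in lexicon:
            raise ValueError(f"mention term {m.term_id!r} not in lexicon")
        if m.status == STATUS_AFFIRMED:
            counts[m.term_id] += 1
    return PatientTally(patient_id=patient_id, occurrences=dict(counts))


def classify_patient(tally: PatientTally, cfg: Optional[ClassifierConfig] = None) -> str:
    """Positive iff the distinct-term count reaches the threshold."""
    cfg = cfg if cfg is not None else ClassifierConfig()
    return POSITIVE if tally.n_distinct >= cfg.threshold else NEGATIVE


def _quartiles(values: Sequence[float]) -> tuple[float, float]:
    # linear interpolation between order statistics ("type 7"), numpy default
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25.0, 75.0])
    return float(q1), float(q3)


def summarize_cohort(tallies: Iterable[PatientTally], group: str) -> CohortSummary:
    """Mean, interquartile range and range of distinct-term counts."""
    values = tuple(t.n_distinct for t in tallies)
    if not values:
        raise ValueError(f"cohort {group!r} is empty")
    q1, q3 = _quartiles(values)
    return CohortSummary(
        group=group,
        values=values,
        mean=float(np.mean(values)),
        q1=q1,
        q3=q3,
        minimum=min(values),
        maximum=max(values),
    )


def term_occurrence_stats(
    tallies: Iterable[PatientTally], term_id: str, group: str
) -> TermStats:
    """Per-patient occurrence counts of one term (0 for absent) with Q1/Q3."""
    counts = tuple(t.occurrences.get(term_id, 0) for t in tallies)
    if not counts:
        raise ValueError(f"cohort {group!r} is empty")
    q1, q3 = _quartiles(counts)
    return TermStats(term_id=term_id, group=group, counts=counts, q1=q1, q3=q3)


def _disjoint(a: TermStats, b: TermStats) -> bool:
    # touching endpoints count as overlap (conservative): strict inequality
    return a.q1 > b.q3 or b.q1 > a.q3


def select_terms_by_iqr(
    candidate_lexicon: Lexicon,
    index_tallies: Sequence[PatientTally],
    control_tallies: Sequence[PatientTally],
) -> frozenset:
    """Retain terms whose index/control occurrence IQRs do not overlap."""
    retained = set()
    for rule in candidate_lexicon:
        idx = term_occurrence_stats(index_tallies, rule.term_id, "index")
        ctl = term_occurrence_stats(control_tallies, rule.term_id, "control")
        if _disjoint(idx, ctl):
            retained.add(rule.term_id)
    return frozenset(retained)


def selection_report(
    candidate_lexicon: Lexicon,
    index_tallies: Sequence[PatientTally],
    control_tallies: Sequence[PatientTally],
) -> pd.DataFrame:
    """Per-term Q1/Q3 for both cohorts and the retention decision."""
    rows = []
    retained = select_terms_by_iqr(candidate_lexicon, index_tallies, control_tallies)
    for rule in candidate_lexicon:
        idx = term_occurrence_stats(index_tallies, rule.term_id, "index")
        ctl = term_occurrence_stats(control_tallies, rule.term_id, "control")
        rows.append(
            {
                "term_id": rule.term_id,
                "index_q1": idx.q1,
                "index_q3": idx.q3,
                "control_q1": ctl.q1,
                "control_q3": ctl.q3,
                "retained": rule.term_id in retained,
            }
        )
    return pd.DataFrame(rows)


def tallies_to_frame(
    tallies: Sequence[PatientTally], predictions: Mapping[str, str]
) -> pd.DataFrame:
    """Per-patient output table: id, distinct count, terms, classification."""
    rows = [
        {
            "patient_id": t.patient_id,
            "n_distinct": t.n_distinct,
            "terms_present": ",".join(sorted(t.terms_present)),
            "classification": predictions[t.patient_id],
        }
        for t in tallies
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "n_distinct", "terms_present", "classification"]
    )
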