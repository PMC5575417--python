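"""End-to-end screening: match → filter → tally → classify."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .context import FilterConfig, apply_filters
from .lexicon import Lexicon, default_lexicon
from .scoring import (
    ClassifierConfig,
    PatientTally,
    classify_patient,
    tally_patient,
)
from .textmatch import ClinicalNote, Mention, find_candidates


@dataclass(frozen=True)
class ScreenResult:
    """Everything the screening pass produced, keyed by patient."""

    mentions: tuple[Mention, ...]
    tallies: Mapping[str, PatientTally]
    predictions: Mapping[str, str]

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(self.tallies)


def screen_corpus(
    notes: Sequence[ClinicalNote],
    lexicon: Optional[Lexicon] = None,
    filter_config: Optional[FilterConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
) -> ScreenResult:
    """Screen a note corpus and classify every patient appearing in it.

    Patients with zero candidate mentions still get a (negative) row.
    Deterministic: output order follows first appearance in the input.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    filter_config = filter_config if filter_config is not None else FilterConfig()
    classifier_config = (
        classifier_config if classifier_config is not None else ClassifierConfig()
    )

    candidates: list[Mention] = []
    for note in notes:
        candidates.extend(find_candidates(note, lexicon))
    filtered = apply_filters(candidates, notes, lexicon, filter_config)

    by_patient: dict[str, list[Mention]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, [])
    for mention in filtered:
        by_patient[mention.patient_id].append(mention)

    tallies = {
        pid: tally_patient(ms, lexicon, patient_id=pid)
        for pid, ms in by_patient.items()
    }
    predictions = {
        pid: classify_patient(t, classifier_config) for pid, t in tallies.items()
    }
    return ScreenResult(
        mentions=tuple(filtered), tallies=tallies, predictions=predictions
    )
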