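"""Seeded synthetic multi-note patient corpora with exact ground truth.

No public corpus of psychosocially annotated clinical notes exists, so the
package ships a generator that emulates the statistical structure the
screener assumes: an index cohort carrying many distinct lexicon terms, a
control cohort carrying few, and the four documented false-positive
confounders (negated mentions, questionnaire/template boilerplate,
family-member mentions, polysemous "AA") injected at configurable per-note
rates. Every emitted mention — true or confounder — is recorded once in the
gold standard, and the generator screens its own carrier sentences against
the lexicon so no stray match can corrupt the gold labels.

Carrier text is short clinical-style boilerplate with a random visit number
per line; it makes no attempt at realistic prose.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .context import FilterConfig
from .evaluation import EvalReport, contingency
from .lexicon import Lexicon, default_lexicon
from .pipeline import screen_corpus
from .scoring import ClassifierConfig, NEGATIVE, POSITIVE
from .textmatch import ClinicalNote, find_candidates, write_notes

TRUTH_TRUE = "true_mention"
TRUTH_NEGATED = "negated"
TRUTH_TEMPLATED = "templated"
TRUTH_MISALLOCATED = "misallocated"
TRUTH_POLYSEMOUS = "polysemous"

#: Terms unusable as confounder payloads: "aa" needs the exact surface "AA"
#: (used only by the polysemy confounder) and "stamps" needs its "food"
#: collocate, so a bare confounder carrier would emit no candidate at all and
#: the mention-level gold standard would drift from the matcher's output.
_CONFOUNDER_EXCLUDED = frozenset({"aa", "stamps"})


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort sizes, burden distributions and confounder rates.

    Defaults mirror the screening study design: 60 index vs 72 control
    patients, index patients carrying 9-22 distinct true terms and controls
    0-8 (uniform), each true term appearing 1-5 times, and each of the four
    confounders emitted per note with probability 0.1.
    """

    n_index: int = 60
    n_control: int = 72
    notes_per_patient: tuple[int, int] = (3, 6)
    burden_index: tuple[int, int] = (9, 22)
    burden_control: tuple[int, int] = (0, 8)
    occurrences_per_term: tuple[int, int] = (1, 5)
    negation_rate: float = 0.1
    template_rate: float = 0.1
    subject_rate: float = 0.1
    polysemy_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("negation_rate", "template_rate", "subject_rate",
                     "polysemy_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1], got {rate}")
        for name in ("notes_per_patient", "burden_index", "burden_control",
                     "occurrences_per_term"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise GeneratorError(f"{name} range ({lo}, {hi}) is invalid")
        if self.notes_per_patient[0] < 1:
            raise GeneratorError("patients need at least one note")
        if self.occurrences_per_term[0] < 1:
            raise GeneratorError("true terms need at least one occurrence")


@dataclass(frozen=True)
class GoldMention:
    patient_id: str
    note_id: str
    term_id: str
    start: int
    end: int
    truth_class: str


@dataclass(frozen=True)
class GoldPatient:
    patient_id: str
    group: str  # "index" | "control"
    true_terms: frozenset


@dataclass(frozen=True)
class GoldStandard:
    patients: Mapping[str, GoldPatient]
    mentions: tuple[GoldMention, ...]

    def labels(self, threshold: int = 9) -> dict[str, str]:
        """Gold positivity: true distinct-term burden reaches the threshold."""
        return {
            pid: POSITIVE if len(p.true_terms) >= threshold else NEGATIVE
            for pid, p in self.patients.items()
        }


def _affirmative_line(term_id: str, surface: str, visit: int) -> tuple[str, int]:
    """Carrier sentence plus char offset of the term within the line."""
    if term_id == "stamps":
        line = f"Relies on food stamps at visit {visit}."
        return line, line.index("stamps")
    if term_id == "aa":
        line = f"Attends AA meeting at visit {visit}."
        return line, line.index("AA")
    line = f"Patient reports {surface} at visit {visit}."
    return line, line.index(surface)


def _confounder_line(kind: str, surface: str, visit: int) -> tuple[str, int]:
    if kind == TRUTH_NEGATED:
        line = f"Patient denies {surface} at visit {visit}."
    elif kind == TRUTH_TEMPLATED:
        line = f"PHQ-9 {surface} screen at visit {visit}: [ ] yes [x] no"
    elif kind == TRUTH_MISALLOCATED:
        line = f"Her son reports {surface} at visit {visit}."
    elif kind == TRUTH_POLYSEMOUS:
        line = f"African American {surface} male at visit {visit}."
    else:  # pragma: no cover - internal
        raise GeneratorError(f"unknown confounder kind {kind!r}")
    return line, line.index(surface)


def _filler_line(rng: random.Random) -> str:
    return f"Seen in clinic at visit {rng.randint(1, 99999)} for routine follow up."


def _verify_note(note: ClinicalNote, lexicon: Lexicon,
                 intended: Sequence[str]) -> None:
    found = sorted(m.term_id for m in find_candidates(note, lexicon))
    if found != sorted(intended):
        raise GeneratorError(
            f"generator self-check failed for note {note.note_id}: "
            f"intended {sorted(intended)}, matcher found {found}"
        )


def generate_corpus(
    cfg: Optional[GeneratorConfig] = None,
    lexicon: Optional[Lexicon] = None,
) -> tuple[list[ClinicalNote], GoldStandard]:
    """Generate notes and an exact gold standard; deterministic given seed."""
    cfg = cfg if cfg is not None else GeneratorConfig()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    term_ids = list(lexicon.term_ids)
    if cfg.burden_index[1] > len(term_ids) or cfg.burden_control[1] > len(term_ids):
        raise GeneratorError(
            f"burden exceeds lexicon size {len(term_ids)}"
        )
    rng = random.Random(cfg.seed)
    confounder_pool = [t for t in term_ids if t not in _CONFOUNDER_EXCLUDED]

    notes: list[ClinicalNote] = []
    gold_patients: dict[str, GoldPatient] = {}
    gold_mentions: list[GoldMention] = []

    groups = [("index", cfg.burden_index)] * cfg.n_index + [
        ("control", cfg.burden_control)
    ] * cfg.n_control
    for p_idx, (group, burden_range) in enumerate(groups):
        pid = f"P{p_idx:04d}"
        burden = rng.randint(*burden_range)
        true_terms = sorted(rng.sample(term_ids, burden))
        gold_patients[pid] = GoldPatient(
            patient_id=pid, group=group, true_terms=frozenset(true_terms)
        )
        n_notes = rng.randint(*cfg.notes_per_patient)
        # (term, occurrence) placements scattered over this patient's notes
        placements: list[list[str]] = [[] for _ in range(n_notes)]
        for term in true_terms:
            for _ in range(rng.randint(*cfg.occurrences_per_term)):
                placements[rng.randrange(n_notes)].append(term)

        open_pool = [t for t in confounder_pool if t not in true_terms]
        for n_idx in range(n_notes):
            note_id = f"{pid}-N{n_idx:02d}"
            # each line: (text, term_id, offset_in_line, truth_class)
            lines: list[tuple[str, Optional[str], int, Optional[str]]] = [
                (_filler_line(rng), None, 0, None)
            ]
            for term in placements[n_idx]:
                surface = lexicon[term].pattern
                text, off = _affirmative_line(term, surface, rng.randint(1, 99999))
                lines.append((text, term, off, TRUTH_TRUE))
            for kind, rate in (
                (TRUTH_NEGATED, cfg.negation_rate),
                (TRUTH_TEMPLATED, cfg.template_rate),
                (TRUTH_MISALLOCATED, cfg.subject_rate),
                (TRUTH_POLYSEMOUS, cfg.polysemy_rate),
            ):
                if rng.random() >= rate:
                    continue
                if kind == TRUTH_POLYSEMOUS:
                    if "aa" in true_terms:
                        continue
                    term, surface = "aa", "AA"
                else:
                    if not open_pool:
                        continue
                    term = rng.choice(open_pool)
                    surface = lexicon[term].pattern
                text, off = _confounder_line(kind, surface, rng.randint(1, 99999))
                lines.append((text, term, off, kind))

            rng.shuffle(lines)
            offset = 0
            parts: list[str] = []
            intended: list[str] = []
            for text, term, off, truth in lines:
                if term is not None:
                    surface = "AA" if term == "aa" else lexicon[term].pattern
                    gold_mentions.append(
                        GoldMention(
                            patient_id=pid,
                            note_id=note_id,
                            term_id=term,
                            start=offset + off,
                            end=offset + off + len(surface),
                            truth_class=truth,
                        )
                    )
                    intended.append(term)
                parts.append(text)
                offset += len(text) + 1  # "\n" join
            note = ClinicalNote(
                patient_id=pid, note_id=note_id, text="\n".join(parts),
                note_type="progress",
            )
            _verify_note(note, lexicon, intended)
            notes.append(note)

    gold = GoldStandard(patients=gold_patients, mentions=tuple(gold_mentions))
    return notes, gold


def write_corpus(
    notes: Sequence[ClinicalNote],
    gold: GoldStandard,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write notes.jsonl, gold_patients.csv and gold_mentions.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "notes": out_dir / "notes.jsonl",
        "gold_patients": out_dir / "gold_patients.csv",
        "gold_mentions": out_dir / "gold_mentions.csv",
    }
    write_notes(notes, paths["notes"])
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "label": POSITIVE if len(p.true_terms) >= 9 else NEGATIVE,
                "true_terms": ",".join(sorted(p.true_terms)),
            }
            for p in gold.patients.values()
        ]
    ).to_csv(paths["gold_patients"], index=False)
    pd.DataFrame([m.__dict__ for m in gold.mentions]).to_csv(
        paths["gold_mentions"], index=False
    )
    return paths


def benchmark_pipeline(
    cfg: Optional[GeneratorConfig] = None,
    classifier_config: Optional[ClassifierConfig] = None,
    lexicon: Optional[Lexicon] = None,
) -> dict[str, EvalReport]:
    """Generate → screen → evaluate, with context filters on and off.

    Returns {"filters_on": ..., "filters_off": ...} evaluated against the
    generator's gold labels; quantifies how much the suppression filters buy
    on a corpus with injected confounders.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    classifier_config = (
        classifier_config if classifier_config is not None else ClassifierConfig()
    )
    lexicon = lexicon if lexicon is not None else default_lexicon()
    notes, gold = generate_corpus(cfg, lexicon)
    gold_labels = gold.labels(threshold=classifier_config.threshold)
    reports = {}
    for name, filter_cfg in (
        ("filters_on", FilterConfig()),
        ("filters_off", FilterConfig(enabled_filters=frozenset())),
    ):
        result = screen_corpus(notes, lexicon, filter_cfg, classifier_config)
        reports[name] = contingency(result.predictions, gold_labels)
    return reports


def generate_selection_corpus(
    discriminative_terms: Sequence[str],
    shared_terms: Sequence[str],
    n_per_group: int = 200,
    high_occurrences: tuple[int, int] = (3, 6),
    low_occurrences: tuple[int, int] = (1, 3),
    notes_per_patient: tuple[int, int] = (2, 4),
    seed: int = 0,
    lexicon: Optional[Lexicon] = None,
) -> tuple[list[ClinicalNote], list[str], list[str]]:
    """Two-cohort corpus for exercising IQR-nonoverlap term selection.

    Index patients carry every discriminative term at a high occurrence
    count plus the shared terms at a low count; controls carry only the
    shared terms at the same low count. With enough patients the
    discriminative terms' occurrence IQRs are disjoint between cohorts while
    the shared terms' IQRs coincide, so selection should recover exactly the
    discriminative set.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    for term in list(discriminative_terms) + list(shared_terms):
        if term not in lexicon:
            raise GeneratorError(f"term {term!r} not in lexicon")
    rng = random.Random(seed)
    notes: list[ClinicalNote] = []
    index_ids: list[str] = []
    control_ids: list[str] = []
    for g_idx, (group, ids) in enumerate(
        (("index", index_ids), ("control", control_ids))
    ):
        for p_idx in range(n_per_group):
            pid = f"S{g_idx}{p_idx:04d}"
            ids.append(pid)
            load: list[str] = []
            if group == "index":
                for term in discriminative_terms:
                    load += [term] * rng.randint(*high_occurrences)
            for term in shared_terms:
                load += [term] * rng.randint(*low_occurrences)
            n_notes = rng.randint(*notes_per_patient)
            placements: list[list[str]] = [[] for _ in range(n_notes)]
            for term in load:
                placements[rng.randrange(n_notes)].append(term)
            for n_idx in range(n_notes):
                lines = [_filler_line(rng)]
                for term in placements[n_idx]:
                    text, _ = _affirmative_line(
                        term, lexicon[term].pattern, rng.randint(1, 99999)
                    )
                    lines.append(text)
                rng.shuffle(lines)
                notes.append(
                    ClinicalNote(
                        patient_id=pid,
                        note_id=f"{pid}-N{n_idx:02d}",
                        text="\n".join(lines),
                    )
                )
    return notes, index_ids, control_ids
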