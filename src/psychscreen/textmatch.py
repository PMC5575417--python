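"""Note ingestion, sentence segmentation, tokenization, candidate mentions.

Notes travel as JSON lines (one object per line with keys ``patient_id``,
``note_id``, optional ``date`` and ``note_type``, and ``text``). Sentences
are the scope for all downstream context filters, so the segmenter treats
``.``, ``!``, ``?``, newline and ``;`` as boundaries, with a guard for
common clinical abbreviations and decimal points. Tokens are maximal
alphanumeric runs; every span is 0-based and half-open in note coordinates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .lexicon import Lexicon, TermRule

#: Mention statuses. A fresh candidate is "affirmed" until a filter demotes it.
STATUS_AFFIRMED = "affirmed"
STATUS_NEGATED = "negated"
STATUS_TEMPLATED = "templated"
STATUS_MISALLOCATED = "misallocated"
STATUS_POLYSEMY = "polysemy_excluded"
MENTION_STATUSES = frozenset(
    {
        STATUS_AFFIRMED,
        STATUS_NEGATED,
        STATUS_TEMPLATED,
        STATUS_MISALLOCATED,
        STATUS_POLYSEMY,
    }
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_TERMINATORS = frozenset(".!?;\n")
#: Tokens whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset(
    {"dr", "mr", "mrs", "ms", "st", "jr", "sr", "prof", "vs", "etc", "fig", "approx"}
)


class NoteError(ValueError):
    """Raised for malformed or inconsistent note input."""


@dataclass(frozen=True)
class ClinicalNote:
    patient_id: str
    note_id: str
    text: str
    date: Optional[str] = None
    note_type: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise NoteError("patient_id must be nonempty")
        if not self.note_id:
            raise NoteError("note_id must be nonempty")


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # note coordinates
    end: int


@dataclass(frozen=True)
class Sentence:
    note_id: str
    index: int
    start: int
    end: int
    tokens: tuple[Token, ...]


@dataclass(frozen=True)
class Mention:
    """One candidate lexicon hit: a (rule, token) pair with a filter status."""

    term_id: str
    patient_id: str
    note_id: str
    sentence_index: int
    token_index: int
    start: int
    end: int
    matched_surface: str
    status: str = STATUS_AFFIRMED

    def __post_init__(self) -> None:
        if self.status not in MENTION_STATUSES:
            raise ValueError(f"unknown mention status {self.status!r}")


def read_notes(path: Union[str, Path]) -> list[ClinicalNote]:
    """Read a JSONL notes file; rejects duplicate (patient_id, note_id) keys."""
    notes: list[ClinicalNote] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise NoteError(f"line {line_no}: invalid JSON ({exc.msg})") from exc
            try:
                note = ClinicalNote(
                    patient_id=str(record["patient_id"]),
                    note_id=str(record["note_id"]),
                    text=str(record["text"]),
                    date=record.get("date"),
                    note_type=record.get("note_type"),
                )
            except KeyError as exc:
                raise NoteError(f"line {line_no}: missing key {exc}") from exc
            key = (note.patient_id, note.note_id)
            if key in seen:
                raise NoteError(f"line {line_no}: duplicate note key {key}")
            seen.add(key)
            notes.append(note)
    return notes


def write_notes(notes: Iterable[ClinicalNote], path: Union[str, Path]) -> None:
    """Write notes as JSONL with sorted keys (byte-stable for a fixed input)."""
    with open(path, "w", encoding="utf-8") as handle:
        for note in notes:
            record = {"patient_id": note.patient_id, "note_id": note.note_id,
                      "text": note.text}
            if note.date is not None:
                record["date"] = note.date
            if note.note_type is not None:
                record["note_type"] = note.note_type
            handle.write(json.dumps(record, sort_keys=True) + "\n")


def _is_guarded_period(text: str, i: int) -> bool:
    # decimal point: digit on both sides
    if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return True
    # trailing period of a known abbreviation
    j = i
    while j > 0 and text[j - 1].isalpha():
        j -= 1
    word = text[j:i]
    return bool(word) and word.lower() in ABBREVIATIONS


def segment_sentences(note: ClinicalNote) -> list[Sentence]:
    """Split a note into non-overlapping, ordered sentences with tokens.

    The concatenation of sentence spans covers all non-whitespace text.
    """
    text = note.text
    raw_spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in _TERMINATORS:
            if ch == "." and _is_guarded_period(text, i):
                continue
            raw_spans.append((start, i + 1))
            start = i + 1
    if start < len(text):
        raw_spans.append((start, len(text)))

    sentences: list[Sentence] = []
    for s, e in raw_spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s == e:
            continue
        tokens = tuple(
            Token(text=m.group(0), start=s + m.start(), end=s + m.end())
            for m in _TOKEN_RE.finditer(text[s:e])
        )
        sentences.append(
            Sentence(note_id=note.note_id, index=len(sentences), start=s, end=e,
                     tokens=tokens)
        )
    return sentences


def _collocate_satisfied(rule: TermRule, tokens: Sequence[Token], j: int) -> bool:
    col = rule.collocate
    if col is None:
        return True
    want = col.token.lower()
    if col.direction == "preceding":
        lo, hi = max(0, j - col.max_distance), j
    else:
        lo, hi = max(0, j - col.max_distance), min(len(tokens), j + col.max_distance + 1)
    return any(
        k != j and tokens[k].text.lower() == want for k in range(lo, hi)
    )


def find_candidates(
    note: ClinicalNote,
    lexicon: Lexicon,
    sentences: Optional[Sequence[Sentence]] = None,
) -> list[Mention]:
    """Scan a note against a lexicon, emitting affirmed candidate mentions.

    One mention per (rule, token position) whose token satisfies the rule's
    match mode, case mode and collocate constraint. Mentions never cross
    sentence boundaries and are returned ordered by character offset.
    """
    if sentences is None:
        sentences = segment_sentences(note)
    mentions: list[Mention] = []
    for sentence in sentences:
        for j, token in enumerate(sentence.tokens):
            for rule in lexicon:
                if not rule.matches_token(token.text):
                    continue
                if not _collocate_satisfied(rule, sentence.tokens, j):
                    continue
                mentions.append(
                    Mention(
                        term_id=rule.term_id,
                        patient_id=note.patient_id,
                        note_id=note.note_id,
                        sentence_index=sentence.index,
                        token_index=j,
                        start=token.start,
                        end=token.end,
                        matched_surface=token.text,
                        status=STATUS_AFFIRMED,
                    )
                )
    mentions.sort(key=lambda m: (m.start, m.term_id))
    return mentions
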