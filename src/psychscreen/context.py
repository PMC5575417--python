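"""False-positive suppression filters for candidate mentions.

Naive token matching in clinical notes produces four recurrent
false-positive modes: negation ("not depressed"), preformatted or template
text (questionnaires, checkbox boilerplate), polysemy ("AA" as amino acid or
African American rather than Alcoholics Anonymous), and misallocation — a
term describing a relative or friend rather than the patient ("her son is in
jail"). Each mode gets one filter; ``apply_filters`` composes them in a
fixed order (template → polysemy → negation → subject) and the first filter
to fire sets the mention's status. Filters only ever rewrite the status:
term identity, span and mention count are conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .lexicon import Lexicon
from .textmatch import (
    STATUS_AFFIRMED,
    STATUS_MISALLOCATED,
    STATUS_NEGATED,
    STATUS_POLYSEMY,
    STATUS_TEMPLATED,
    ClinicalNote,
    Mention,
    Sentence,
    segment_sentences,
)

FILTER_NAMES = ("template", "polysemy", "negation", "subject")

DEFAULT_NEGATION_TRIGGERS = ("no", "not", "denies", "denied", "without", "never")
DEFAULT_NEGATION_BIGRAMS = (("negative", "for"),)
DEFAULT_SUBJECT_CUES = (
    "son", "daughter", "mother", "father", "brother", "sister",
    "husband", "wife", "friend", "family", "partner", "neighbor",
)
#: Regexes (case-insensitive) marking a line as preformatted/template text:
#: checkbox glyphs and questionnaire vocabulary.
DEFAULT_TEMPLATE_MARKERS = (
    r"\[\s*[xX]?\s*\]",
    r"\bscreen(?:ing|s|ed)?\b",
    r"\bquestionnaires?\b",
    r"\bphq\b",
    r"\bforms?\b",
    r"\bchecklists?\b",
    r"denies all of the following",
)


class FilterConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Trigger lists, token windows and enabled-filter set.

    Windows count tokens between trigger/cue and term within one sentence;
    both filters look only BEFORE the term (post-negated checkbox lines are
    the template filter's job). ``template_repeat_threshold`` is the number
    of distinct notes in which an identical line must appear before it is
    treated as boilerplate.
    """

    negation_triggers: tuple[str, ...] = DEFAULT_NEGATION_TRIGGERS
    negation_bigrams: tuple[tuple[str, str], ...] = DEFAULT_NEGATION_BIGRAMS
    negation_window: int = 5
    subject_cues: tuple[str, ...] = DEFAULT_SUBJECT_CUES
    subject_window: int = 5
    template_markers: tuple[str, ...] = DEFAULT_TEMPLATE_MARKERS
    template_repeat_threshold: int = 5
    enabled_filters: frozenset = frozenset(FILTER_NAMES)

    def __post_init__(self) -> None:
        if self.negation_window < 1 or self.subject_window < 1:
            raise FilterConfigError("windows must be positive integers")
        if self.template_repeat_threshold < 1:
            raise FilterConfigError("template_repeat_threshold must be positive")
        unknown = set(self.enabled_filters) - set(FILTER_NAMES)
        if unknown:
            raise FilterConfigError(f"unknown filter names {sorted(unknown)}")
        object.__setattr__(self, "enabled_filters", frozenset(self.enabled_filters))

    def compiled_markers(self) -> tuple[re.Pattern, ...]:
        return tuple(re.compile(p, re.IGNORECASE) for p in self.template_markers)


def _cue_before(
    mention: Mention,
    sentence: Sentence,
    cues: Iterable[str],
    window: int,
    bigrams: Sequence[tuple[str, str]] = (),
) -> bool:
    j = mention.token_index
    lo = max(0, j - window)
    lowered = [t.text.lower() for t in sentence.tokens[lo:j]]
    cue_set = set(cues)
    if any(tok in cue_set for tok in lowered):
        return True
    for first, second in bigrams:
        for k in range(len(lowered) - 1):
            if lowered[k] == first and lowered[k + 1] == second:
                return True
    return False


def filter_negation(mention: Mention, sentence: Sentence, cfg: FilterConfig) -> Mention:
    """Mark a mention negated when a negation trigger precedes it in-sentence."""
    if mention.status != STATUS_AFFIRMED:
        return mention
    if _cue_before(mention, sentence, cfg.negation_triggers, cfg.negation_window,
                   cfg.negation_bigrams):
        return replace(mention, status=STATUS_NEGATED)
    return mention


def filter_subject(mention: Mention, sentence: Sentence, cfg: FilterConfig) -> Mention:
    """Mark a mention misallocated when a non-patient subject cue precedes it."""
    if mention.status != STATUS_AFFIRMED:
        return mention
    if _cue_before(mention, sentence, cfg.subject_cues, cfg.subject_window):
        return replace(mention, status=STATUS_MISALLOCATED)
    return mention


def filter_polysemy(mention: Mention, sentence: Sentence, lexicon: Lexicon) -> Mention:
    """Veto a mention whose rule has an exclusion cue in the same sentence."""
    if mention.status != STATUS_AFFIRMED:
        return mention
    cues = {c.lower() for c in lexicon[mention.term_id].exclusion_cues}
    if not cues:
        return mention
    tokens = {t.text.lower() for t in sentence.tokens}
    if tokens & cues:
        return replace(mention, status=STATUS_POLYSEMY)
    return mention


def _line_of(text: str, pos: int) -> str:
    start = text.rfind("\n", 0, pos) + 1
    end = text.find("\n", pos)
    if end == -1:
        end = len(text)
    return text[start:end]


def filter_template(
    mention: Mention,
    note: ClinicalNote,
    cfg: FilterConfig,
    repeated_lines: frozenset = frozenset(),
    _markers: Optional[tuple[re.Pattern, ...]] = None,
) -> Mention:
    """Mark a mention templated when its line looks like boilerplate.

    A line is boilerplate when it matches a template marker pattern or when
    the identical (stripped) line recurs across enough distinct notes
    (``repeated_lines`` is that precomputed set; ``apply_filters`` builds it
    from the corpus).
    """
    if mention.status != STATUS_AFFIRMED:
        return mention
    line = _line_of(note.text, mention.start)
    markers = _markers if _markers is not None else cfg.compiled_markers()
    if any(marker.search(line) for marker in markers):
        return replace(mention, status=STATUS_TEMPLATED)
    if line.strip() in repeated_lines:
        return replace(mention, status=STATUS_TEMPLATED)
    return mention


def repeated_lines_across_notes(
    notes: Iterable[ClinicalNote], threshold: int
) -> frozenset:
    """Stripped lines occurring in at least ``threshold`` distinct notes."""
    notes_per_line: dict[str, set[str]] = {}
    for note in notes:
        for raw in note.text.split("\n"):
            line = raw.strip()
            if line:
                notes_per_line.setdefault(line, set()).add(
                    (note.patient_id, note.note_id))
    return frozenset(
        line for line, ids in notes_per_line.items() if len(ids) >= threshold
    )


def apply_filters(
    mentions: Iterable[Mention],
    notes: Iterable[ClinicalNote],
    lexicon: Lexicon,
    cfg: Optional[FilterConfig] = None,
) -> list[Mention]:
    """Run the enabled filters over all mentions in fixed order.

    Order is template → polysemy → negation → subject; the first enabled
    filter to fire sets the status and later filters leave it alone. With no
    enabled filters the output statuses equal the input's.
    """
    cfg = cfg if cfg is not None else FilterConfig()
    notes = list(notes)
    note_map: Mapping[tuple, ClinicalNote] = {
        (n.patient_id, n.note_id): n for n in notes
    }
    sentence_map: dict[tuple, list[Sentence]] = {
        key: segment_sentences(n) for key, n in note_map.items()
    }
    enabled = cfg.enabled_filters
    repeated = (
        repeated_lines_across_notes(notes, cfg.template_repeat_threshold)
        if "template" in enabled
        else frozenset()
    )
    markers = cfg.compiled_markers()

    out: list[Mention] = []
    for mention in mentions:
        key = (mention.patient_id, mention.note_id)
        note = note_map[key]
        sentence = sentence_map[key][mention.sentence_index]
        if "template" in enabled:
            mention = filter_template(mention, note, cfg, repeated, markers)
        if "polysemy" in enabled:
            mention = filter_polysemy(mention, sentence, lexicon)
        if "negation" in enabled:
            mention = filter_negation(mention, sentence, cfg)
        if "subject" in enabled:
            mention = filter_subject(mention, sentence, cfg)
        out.append(mention)
    return out
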