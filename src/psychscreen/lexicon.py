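"""Psychosocial risk lexicon: term rules, validation, TSV I/O.

A lexicon is an ordered collection of single-token search rules, each tagged
with one of four psychosocial domains (mental health, substance use, social
determinants, legal history). The packaged default lexicon holds the 22 terms
whose presence across a patient's notes drives the screening classifier.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

MATCH_MODES = frozenset({"exact_token", "prefix_token"})
CASE_MODES = frozenset({"insensitive", "exact"})
DOMAINS = frozenset(
    {"mental_health", "substance_use", "social_determinants", "legal_history"}
)
COLLOCATE_DIRECTIONS = frozenset({"preceding", "any"})

_COLUMNS = (
    "term_id",
    "pattern",
    "match_mode",
    "case_mode",
    "domain",
    "collocate",
    "exclusion_cues",
)


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon content."""


@dataclass(frozen=True)
class Collocate:
    """A required neighboring token.

    ``token`` must occur within ``max_distance`` tokens of the term in the
    same sentence; ``direction`` restricts where it may sit ("preceding"
    means strictly before the term).
    """

    token: str
    max_distance: int
    direction: str = "preceding"

    def __post_init__(self) -> None:
        if self.max_distance < 1:
            raise LexiconError(
                f"collocate max_distance must be positive, got {self.max_distance}"
            )
        if self.direction not in COLLOCATE_DIRECTIONS:
            raise LexiconError(f"unknown collocate direction {self.direction!r}")

    def to_field(self) -> str:
        return f"{self.token}:{self.max_distance}:{self.direction}"

    @classmethod
    def from_field(cls, text: str) -> "Collocate":
        parts = text.split(":")
        if len(parts) == 2:
            token, dist = parts
            direction = "preceding"
        elif len(parts) == 3:
            token, dist, direction = parts
        else:
            raise LexiconError(f"malformed collocate field {text!r}")
        try:
            distance = int(dist)
        except ValueError as exc:
            raise LexiconError(f"malformed collocate distance in {text!r}") from exc
        return cls(token=token, max_distance=distance, direction=direction)


@dataclass(frozen=True)
class TermRule:
    """One lexicon entry: a surface pattern plus its matching semantics."""

    term_id: str
    pattern: str
    match_mode: str = "exact_token"
    case_mode: str = "insensitive"
    domain: str = "mental_health"
    collocate: Optional[Collocate] = None
    exclusion_cues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term_id:
            raise LexiconError("term_id must be nonempty")
        if not self.pattern:
            raise LexiconError(f"rule {self.term_id!r} has empty pattern")
        if self.match_mode not in MATCH_MODES:
            raise LexiconError(
                f"rule {self.term_id!r}: unknown match_mode {self.match_mode!r}"
            )
        if self.case_mode not in CASE_MODES:
            raise LexiconError(
                f"rule {self.term_id!r}: unknown case_mode {self.case_mode!r}"
            )
        if self.domain not in DOMAINS:
            raise LexiconError(
                f"rule {self.term_id!r}: unknown domain {self.domain!r}"
            )

    def matches_token(self, token_text: str) -> bool:
        """Whether a single surface token satisfies pattern/mode/case."""
        if self.case_mode == "exact":
            token, pattern = token_text, self.pattern
        else:
            token, pattern = token_text.lower(), self.pattern.lower()
        if self.match_mode == "exact_token":
            return token == pattern
        return token.startswith(pattern)


@dataclass(frozen=True)
class Lexicon:
    """An ordered, uniquely keyed collection of term rules."""

    rules: tuple[TermRule, ...]
    name: str = "lexicon"
    version: str = "1"
    _by_id: dict = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        by_id = {}
        for rule in self.rules:
            if rule.term_id in by_id:
                raise LexiconError(f"duplicate term_id {rule.term_id!r}")
            by_id[rule.term_id] = rule
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[TermRule]:
        return iter(self.rules)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def __getitem__(self, term_id: str) -> TermRule:
        return self._by_id[term_id]

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(rule.term_id for rule in self.rules)


def _parse_row(row: Sequence[str], line_no: int) -> TermRule:
    padded = list(row) + [""] * (len(_COLUMNS) - len(row))
    if len(padded) > len(_COLUMNS):
        raise LexiconError(
            f"line {line_no}: expected at most {len(_COLUMNS)} columns, got {len(row)}"
        )
    values = dict(zip(_COLUMNS, padded))
    try:
        collocate = (
            Collocate.from_field(values["collocate"]) if values["collocate"] else None
        )
        cues = tuple(
            cue.strip() for cue in values["exclusion_cues"].split(",") if cue.strip()
        )
        return TermRule(
            term_id=values["term_id"],
            pattern=values["pattern"],
            match_mode=values["match_mode"],
            case_mode=values["case_mode"],
            domain=values["domain"],
            collocate=collocate,
            exclusion_cues=cues,
        )
    except LexiconError as exc:
        raise LexiconError(f"line {line_no}: {exc}") from exc


def _load_from_text(text: str, name: str) -> Lexicon:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise LexiconError("lexicon file is empty (missing header row)")
    if tuple(header[: len(_COLUMNS)]) != _COLUMNS:
        raise LexiconError(
            f"unexpected header {header!r}; expected columns {list(_COLUMNS)}"
        )
    rules = []
    seen: set[str] = set()
    for line_no, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        rule = _parse_row(row, line_no)
        if rule.term_id in seen:
            raise LexiconError(f"line {line_no}: duplicate term_id {rule.term_id!r}")
        seen.add(rule.term_id)
        rules.append(rule)
    return Lexicon(rules=tuple(rules), name=name)


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load and validate a TSV lexicon file.

    Raises ``FileNotFoundError`` for a missing file and ``LexiconError``
    (naming the offending line) for malformed rows, unknown enum values, or
    duplicate term ids.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return _load_from_text(text, name=path.stem)


def save_lexicon(lexicon: Lexicon, path: Union[str, Path]) -> None:
    """Write a lexicon to TSV; ``load_lexicon`` round-trips it exactly."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_COLUMNS)
        for rule in lexicon:
            writer.writerow(
                [
                    rule.term_id,
                    rule.pattern,
                    rule.match_mode,
                    rule.case_mode,
                    rule.domain,
                    rule.collocate.to_field() if rule.collocate else "",
                    ",".join(rule.exclusion_cues),
                ]
            )


def default_lexicon() -> Lexicon:
    """The packaged 22-term psychosocial risk lexicon.

    Terms span four domains: mental health (anxiety, depressed, sad, angry,
    neurovegetative, schizoaffective), substance use (substance, abuse,
    addict, aa, sober, cocaine, heroin, crack, mushrooms, tox), legal history
    (prison, jail, stolen) and social determinants (homeless, shelter,
    stamps). "AA" matches case-exactly with amino-acid / African-American
    exclusion cues; "stamps" requires a preceding "food"; "tox" is
    exact-token so "toxicity" does not fire.
    """
    text = (
        resources.files("psychscreen.data")
        .joinpath("default_lexicon.tsv")
        .read_text(encoding="utf-8")
    )
    lexicon = _load_from_text(text, name="default")
    return replace(lexicon, name="psychosocial-22", version="1")
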