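import dataclasses
import itertools

import pytest

from psychscreen import apply_filters, find_candidates, segment_sentences
from psychscreen.context import (
    FilterConfig,
    FilterConfigError,
    filter_negation,
    filter_polysemy,
    filter_subject,
    filter_template,
    repeated_lines_across_notes,
)
from psychscreen.textmatch import ClinicalNote

from conftest import make_note


def one_mention(text, lexicon, term_id=None):
    note = make_note(text)
    sentences = segment_sentences(note)
    mentions = find_candidates(note, lexicon, sentences)
    if term_id is not None:
        mentions = [m for m in mentions if m.term_id == term_id]
    assert len(mentions) == 1, mentions
    return note, sentences, mentions[0]


# --- negation ---------------------------------------------------------------

@pytest.mark.parametrize(
    "text, term, expected",
    [
        ("patient is not depressed", "depressed", "negated"),
        ("denies cocaine use", "cocaine", "negated"),
        # trigger 3 tokens before the term: inside the default window of 5
        ("not hungry but depressed", "depressed", "negated"),
        ("without any heroin use", "heroin", "negated"),
        ("negative for cocaine", "cocaine", "negated"),
        ("pt tearful and depressed today", "depressed", "affirmed"),
        # trigger after the term does not negate
        ("depressed he is not", "depressed", "affirmed"),
    ],
)
def test_negation_scenarios(lexicon, text, term, expected):
    note, sentences, m = one_mention(text, lexicon, term)
    out = filter_negation(m, sentences[m.sentence_index], FilterConfig())
    assert out.status == expected


def test_negation_window_arithmetic(lexicon):
    # trigger exactly 6 tokens before the term: outside window 5, inside 6
    text = "not a b c d e depressed"
    note, sentences, m = one_mention(text, lexicon, "depressed")
    sent = sentences[m.sentence_index]
    assert filter_negation(m, sent, FilterConfig(negation_window=5)).status == "affirmed"
    assert filter_negation(m, sent, FilterConfig(negation_window=6)).status == "negated"


def test_negation_does_not_cross_sentence_boundary(lexicon):
    note, sentences, m = one_mention("no problems. cocaine use ongoing", lexicon)
    out = filter_negation(m, sentences[m.sentence_index], FilterConfig())
    assert out.status == "affirmed"


# --- template ---------------------------------------------------------------

def test_template_marker_line(lexicon):
    note, _, m = one_mention("PHQ-9 depressed screen: [ ] yes [x] no", lexicon,
                             "depressed")
    assert filter_template(m, note, FilterConfig()).status == "templated"


def test_free_prose_line_not_templated(lexicon):
    note, _, m = one_mention("pt tearful and depressed today", lexicon)
    assert filter_template(m, note, FilterConfig()).status == "affirmed"


def test_boilerplate_repetition_across_notes(lexicon):
    line = "Denies: anxiety, substance abuse"
    notes = [ClinicalNote("p%d" % i, "n%d" % i, line) for i in range(6)]
    repeated = repeated_lines_across_notes(notes, threshold=5)
    assert line in repeated
    mentions = find_candidates(notes[0], lexicon)
    out = [filter_template(m, notes[0], FilterConfig(), repeated) for m in mentions]
    assert {m.status for m in out} == {"templated"}
    # below threshold the same line passes
    few = notes[:4]
    assert repeated_lines_across_notes(few, threshold=5) == frozenset()


def test_repetition_applied_via_apply_filters(lexicon):
    line = "Denies: anxiety, substance abuse"
    notes = [ClinicalNote(f"p{i}", f"n{i}", line) for i in range(6)]
    mentions = list(itertools.chain.from_iterable(
        find_candidates(n, lexicon) for n in notes))
    out = apply_filters(mentions, notes, lexicon,
                        FilterConfig(enabled_filters=frozenset({"template"})))
    assert all(m.status == "templated" for m in out)


# --- polysemy ---------------------------------------------------------------

def test_polysemy_cue_vetoes(lexicon):
    note, sentences, m = one_mention("African American AA male", lexicon)
    out = filter_polysemy(m, sentences[m.sentence_index], lexicon)
    assert out.status == "polysemy_excluded"


def test_polysemy_without_cue_unchanged(lexicon):
    note, sentences, m = one_mention("attends AA twice weekly", lexicon)
    assert filter_polysemy(m, sentences[m.sentence_index], lexicon).status == "affirmed"


def test_polysemy_no_cues_never_fires(lexicon):
    note, sentences, m = one_mention("amino acid heroin panel", lexicon, "heroin")
    assert filter_polysemy(m, sentences[m.sentence_index], lexicon).status == "affirmed"


# --- subject ----------------------------------------------------------------

@pytest.mark.parametrize(
    "text, term, expected",
    [
        ("her son is in jail", "jail", "misallocated"),
        ("pt was in jail last year", "jail", "affirmed"),
        ("mother struggles with heroin", "heroin", "misallocated"),
    ],
)
def test_subject_scenarios(lexicon, text, term, expected):
    note, sentences, m = one_mention(text, lexicon, term)
    assert filter_subject(m, sentences[m.sentence_index],
                          FilterConfig()).status == expected


def test_semicolon_scopes_subject_attribution(lexicon):
    note = make_note("brother uses heroin; pt uses cocaine")
    out = apply_filters(find_candidates(note, lexicon), [note], lexicon,
                        FilterConfig())
    by_term = {m.term_id: m.status for m in out}
    assert by_term == {"heroin": "misallocated", "cocaine": "affirmed"}


# --- composition ------------------------------------------------------------

def test_disabled_filters_are_identity(lexicon):
    note = make_note("her son denies cocaine\nPHQ-9 depressed screen")
    mentions = find_candidates(note, lexicon)
    out = apply_filters(mentions, [note], lexicon,
                        FilterConfig(enabled_filters=frozenset()))
    assert out == mentions


def test_filter_order_template_wins_over_negation(lexicon):
    # line is both a questionnaire marker and a negated context
    note = make_note("denies depressed on PHQ screen")
    out = apply_filters(find_candidates(note, lexicon), [note], lexicon,
                        FilterConfig())
    assert [m.status for m in out] == ["templated"]


def test_filters_conserve_count_term_and_span(lexicon):
    note = make_note(
        "her son denies cocaine. African American AA male. not depressed.\n"
        "PHQ-9 anxiety screen"
    )
    mentions = find_candidates(note, lexicon)
    out = apply_filters(mentions, [note], lexicon, FilterConfig())
    assert len(out) == len(mentions)
    assert [(m.term_id, m.start, m.end) for m in out] == \
        [(m.term_id, m.start, m.end) for m in mentions]


def test_apply_filters_idempotent_and_deterministic(lexicon):
    note = make_note("her son denies cocaine. not depressed. attends AA")
    cfg = FilterConfig()
    once = apply_filters(find_candidates(note, lexicon), [note], lexicon, cfg)
    twice = apply_filters(once, [note], lexicon, cfg)
    assert once == twice


def test_disabling_a_filter_never_decreases_affirmed(lexicon):
    note = make_note(
        "her son denies cocaine. African American AA male. not depressed.\n"
        "PHQ-9 anxiety screen. pt reports heroin use"
    )
    mentions = find_candidates(note, lexicon)
    full = apply_filters(mentions, [note], lexicon, FilterConfig())
    n_full = sum(m.status == "affirmed" for m in full)
    for dropped in ("template", "polysemy", "negation", "subject"):
        cfg = FilterConfig(
            enabled_filters=frozenset(
                {"template", "polysemy", "negation", "subject"}) - {dropped})
        out = apply_filters(mentions, [note], lexicon, cfg)
        assert sum(m.status == "affirmed" for m in out) >= n_full


def test_filter_config_validation():
    with pytest.raises(FilterConfigError):
        FilterConfig(negation_window=0)
    with pytest.raises(FilterConfigError):
        FilterConfig(enabled_filters=frozenset({"negation", "dates"}))
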