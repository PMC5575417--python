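import dataclasses
import random

import numpy as np
import pytest

from psychscreen import (
    ClassifierConfig,
    classify_patient,
    select_terms_by_iqr,
    selection_report,
    summarize_cohort,
    tally_patient,
    term_occurrence_stats,
)
from psychscreen.scoring import PatientTally
from psychscreen.textmatch import Mention

from conftest import make_note


def mk_mention(term, status="affirmed", pid="p1", start=0):
    return Mention(term_id=term, patient_id=pid, note_id="n1", sentence_index=0,
                   token_index=0, start=start, end=start + len(term),
                   matched_surface=term, status=status)


def mk_tally(pid, occurrences):
    return PatientTally(patient_id=pid, occurrences=occurrences)


# --- tallying ---------------------------------------------------------------

def test_distinct_term_tally_ignores_raw_counts(lexicon):
    mentions = [mk_mention("heroin", start=i * 10) for i in range(7)]
    mentions.append(mk_mention("homeless", start=100))
    tally = tally_patient(mentions, lexicon)
    assert tally.n_distinct == 2
    assert tally.occurrences == {"heroin": 7, "homeless": 1}
    assert tally.terms_present == {"heroin", "homeless"}


def test_non_affirmed_mentions_do_not_count(lexicon):
    mentions = [
        mk_mention("heroin", status="negated"),
        mk_mention("cocaine", status="templated", start=10),
        mk_mention("jail", status="misallocated", start=20),
        mk_mention("aa", status="polysemy_excluded", start=30),
    ]
    tally = tally_patient(mentions, lexicon, patient_id="p1")
    assert tally.n_distinct == 0


def test_empty_tally_requires_patient_id(lexicon):
    assert tally_patient([], lexicon, patient_id="p9").n_distinct == 0
    with pytest.raises(ValueError):
        tally_patient([], lexicon)


def test_tally_upper_bound_all_terms(lexicon):
    mentions = [mk_mention(t, start=i * 30) for i, t in enumerate(lexicon.term_ids)]
    assert tally_patient(mentions, lexicon).n_distinct == 22


def test_tally_invariant_to_mention_order(lexicon):
    mentions = [mk_mention(t, start=i * 10)
                for i, t in enumerate(["sad", "heroin", "sad", "jail"])]
    rng = random.Random(0)
    shuffled = mentions[:]
    rng.shuffle(shuffled)
    assert tally_patient(mentions, lexicon) == tally_patient(shuffled, lexicon)


# --- classification ---------------------------------------------------------

@pytest.mark.parametrize("n_distinct, threshold, expected", [
    (9, 9, "positive"),
    (8, 9, "negative"),
    (22, 9, "positive"),
    (22, 22, "positive"),
    (0, 1, "negative"),
])
def test_positivity_threshold(n_distinct, threshold, expected):
    tally = mk_tally("p1", {f"t{i}": 1 for i in range(n_distinct)})
    assert classify_patient(tally, ClassifierConfig(threshold=threshold)) == expected


def test_classification_monotone_in_added_terms(lexicon):
    cfg = ClassifierConfig(threshold=9)
    occurrences = {}
    was_positive = False
    for term in lexicon.term_ids:
        occurrences[term] = 1
        label = classify_patient(mk_tally("p", dict(occurrences)), cfg)
        if was_positive:
            assert label == "positive"
        was_positive = label == "positive"


def test_threshold_must_be_positive():
    with pytest.raises(ValueError):
        ClassifierConfig(threshold=0)


# --- cohort summaries -------------------------------------------------------

def test_summary_small_cohort():
    tallies = [mk_tally(f"p{i}", {f"t{j}": 1 for j in range(v)})
               for i, v in enumerate([2, 2, 3])]
    s = summarize_cohort(tallies, "pediatric")
    assert s.mean == pytest.approx(7 / 3)
    assert (s.minimum, s.maximum) == (2, 3)


def test_summary_singleton():
    s = summarize_cohort([mk_tally("p", {f"t{j}": 1 for j in range(5)})], "g")
    assert (s.mean, s.q1, s.q3, s.minimum, s.maximum) == (5.0, 5.0, 5.0, 5, 5)


def test_summary_empty_cohort_errors():
    with pytest.raises(ValueError):
        summarize_cohort([], "g")


def test_summary_monte_carlo_matches_distribution():
    rng = np.random.default_rng(12345)
    draws = rng.integers(0, 23, size=1000)  # uniform on 0..22
    tallies = [mk_tally(f"p{i}", {f"t{j}": 1 for j in range(int(v))})
               for i, v in enumerate(draws)]
    s = summarize_cohort(tallies, "sim")
    assert s.mean == pytest.approx(11.0, abs=0.7)  # ~3 sigma of SE
    assert abs(s.q1 - 5.5) <= 1.0 and abs(s.q3 - 16.5) <= 1.0
    assert s.minimum == 0 and s.maximum == 22


# --- per-term stats and IQR selection ---------------------------------------

def test_term_stats_quartiles():
    tallies = [mk_tally("a", {}), mk_tally("b", {}),
               mk_tally("c", {"sad": 1}), mk_tally("d", {"sad": 3})]
    stats = term_occurrence_stats(tallies, "sad", "g")
    assert stats.counts == (0, 0, 1, 3)
    assert stats.q1 == pytest.approx(0.0)
    assert stats.q3 == pytest.approx(1.5)


def test_term_stats_constant_and_singleton():
    zeros = [mk_tally(f"p{i}", {}) for i in range(4)]
    s = term_occurrence_stats(zeros, "sad", "g")
    assert (s.q1, s.q3) == (0.0, 0.0)
    single = term_occurrence_stats([mk_tally("p", {"sad": 4})], "sad", "g")
    assert (single.q1, single.q3) == (4.0, 4.0)


def _cohort_with_counts(term, counts, prefix):
    return [mk_tally(f"{prefix}{i}", {term: c} if c else {})
            for i, c in enumerate(counts)]


def test_iqr_selection_disjoint_vs_overlapping(lexicon):
    # "sad": index counts IQR [3,6], control [0,1] -> retained
    # "jail": index [2,5], control [4,7] -> dropped
    index = [mk_tally(f"i{k}", {"sad": s, "jail": j})
             for k, (s, j) in enumerate(zip([3, 4, 5, 6], [2, 3, 4, 5]))]
    control = [mk_tally(f"c{k}", {"sad": s, "jail": j})
               for k, (s, j) in enumerate(zip([0, 0, 1, 1], [3, 4, 5, 6]))]
    retained = select_terms_by_iqr(lexicon, index, control)
    assert "sad" in retained
    assert "jail" not in retained


def test_iqr_touching_endpoints_count_as_overlap(lexicon):
    index = _cohort_with_counts("sad", [2, 2, 2, 2], "i")
    control = _cohort_with_counts("sad", [2, 2, 2, 2], "c")
    assert "sad" not in select_terms_by_iqr(lexicon, index, control)


def test_iqr_selection_symmetric_under_group_swap(lexicon):
    rng = random.Random(5)
    index = [mk_tally(f"i{k}", {"sad": rng.randint(3, 6), "jail": rng.randint(0, 2)})
             for k in range(30)]
    control = [mk_tally(f"c{k}", {"sad": rng.randint(0, 1)}) for k in range(30)]
    assert select_terms_by_iqr(lexicon, index, control) == \
        select_terms_by_iqr(lexicon, control, index)


def test_selection_report_columns(lexicon):
    index = _cohort_with_counts("sad", [3, 4, 5, 6], "i")
    control = _cohort_with_counts("sad", [0, 0, 1, 1], "c")
    report = selection_report(lexicon, index, control)
    assert list(report.columns) == ["term_id", "index_q1", "index_q3",
                                    "control_q1", "control_q3", "retained"]
    assert len(report) == 22
    row = report.set_index("term_id").loc["sad"]
    assert bool(row["retained"])
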