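# psychscreen

Lexicon-based screening of free-text clinical notes for psychosocial risk.

Psychosocial drivers of health — housing and food insecurity, mental health
conditions, substance use, legal history — rarely live in structured EHR
fields or claims data, so patients who would benefit from care coordination
are hard to find with the usual code-based algorithms. `psychscreen`
implements a word-recognition screening algorithm for exactly this problem:
it scans every note in a patient's record for a 22-term psychosocial
lexicon, suppresses the four false-positive modes that plague naive term
matching in clinical text, and calls a patient screen-positive when enough
*distinct* risk terms are affirmed.

The package is aimed at health-informatics researchers and care-coordination
analysts who need a transparent, auditable, rule-based screener — and a way
to test one without access to protected patient data.

## The algorithm

For each patient with notes $d_1, \dots, d_m$ and lexicon terms
$t_1, \dots, t_{22}$:

1. **Match.** Tokenize each note and emit a candidate mention for every
   token matching a term rule (exact-token or prefix-token, case-folded
   unless the rule is case-exact, e.g. "AA"; "stamps" additionally requires
   a preceding "food").
2. **Filter.** Demote candidates in suppressing contexts, in fixed order:
   *template* (questionnaire/checkbox lines, or identical lines recurring in
   ≥ 5 distinct notes), *polysemy* (exclusion cue in the sentence, e.g.
   "amino"/"African" near "AA"), *negation* (trigger such as
   no/not/denies/without within 5 tokens before the term), *subject*
   (family-member cue such as son/mother within 5 tokens before the term).
3. **Tally.** Count the distinct terms with ≥ 1 affirmed mention anywhere in
   the record: $x = |\{ j : \text{term } t_j \text{ affirmed} \}|$.
   Categories, not raw counts, so one frequently documented problem cannot
   cross the threshold on volume.
4. **Classify.** Screen-positive iff $x \ge 9$.

Against a gold label the screen is evaluated with the standard contingency
metrics: accuracy $(TP+TN)/N$, precision $TP/(TP+FP)$, recall $TP/(TP+FN)$
and balanced F-measure $2PR/(P+R)$. Candidate terms are selected by the
IQR-nonoverlap rule: a term is kept only when the interquartile intervals of
its per-patient occurrence counts in index vs control cohorts are disjoint.

A seeded synthetic-corpus generator (`psychscreen.synthetic`) emulates the
study design — a high-burden index cohort, a low-burden control cohort, and
all four confounders injected at configurable rates with an exact
mention-level gold standard — so the whole pipeline is testable end to end.

## Worked example

```python
from psychscreen import ClinicalNote, screen_corpus, tallies_to_frame

notes = [
    ClinicalNote("alice", "visit-1",
                 "Pt reports heroin and cocaine use. Currently homeless, "
                 "staying in a shelter. Reports anxiety, feeling sad and "
                 "angry. Attends AA. History of substance abuse and prison."),
    ClinicalNote("bob", "visit-1",
                 "Denies cocaine use. Her son is in jail.\n"
                 "PHQ-9 depressed screen: [ ] yes [x] no"),
]
result = screen_corpus(notes)
print(tallies_to_frame(list(result.tallies.values()), result.predictions))
```

prints

```
patient_id  n_distinct                                                               terms_present classification
     alice          11 aa,abuse,angry,anxiety,cocaine,heroin,homeless,prison,sad,shelter,substance       positive
       bob           0                                                                                   negative
```

alice has 11 distinct affirmed terms, so she crosses the ≥ 9 threshold. All
three of bob's candidate mentions are suppressed — "cocaine" is negated
("Denies"), "jail" is misallocated to a relative ("Her son"), and
"depressed" sits on a questionnaire line — so he tallies 0 and screens
negative.

The `examples/` directory has one short script per capability (screening,
filter benchmarking, IQR term selection, cohort summaries), and the same
pipeline is available from the shell:

```bash
psychscreen simulate --out-dir sim --seed 7
psychscreen screen --notes sim/notes.jsonl --out screen.csv
psychscreen evaluate --predictions screen.csv --gold sim/gold_patients.csv --out eval.json
```

## Documentation

`docs/methods.md` describes the model and its assumptions, every tunable
parameter with its default and rationale, what the synthetic generator does
and does not emulate, and known limitations.
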