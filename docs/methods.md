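# Methods

## The screening model

`psychscreen` screens a patient's complete free-text record for psychosocial
risk with a fixed 22-term lexicon spanning four domains: mental health
(anxiety, depressed, sad, angry, neurovegetative, schizoaffective),
substance use (substance, abuse, addict, aa, sober, cocaine, heroin, crack,
mushrooms, tox), legal history (prison, jail, stolen) and social
determinants (homeless, shelter, stamps). The decision statistic is the
number of **distinct** lexicon terms with at least one affirmed mention
anywhere in the record; a patient is screen-positive when that count reaches
the threshold (default 9). Counting categories rather than raw occurrences
is deliberate: a patient whose single problem is densely documented (severe
anxiety at every visit), or a patient accumulating one recurring
false-positive source (yearly depression questionnaires), should not cross
the threshold on volume alone.

The model's assumptions, made explicit:

- risk terms are single alphanumeric tokens; multi-word concepts are out of
  scope (the lexicon's one contextual constraint, food→stamps, is expressed
  as a collocate, not a phrase);
- suppressing context is sentence-local (negation, polysemy, subject) or
  line-local (template text);
- mentions have no dates — recency is intentionally ignored because carried-
  forward note text and pre-typed templates make date metadata unreliable;
- the gold label is a binary judgment per patient (e.g. eligibility for a
  care coordination program), evaluated with a 2×2 contingency table.

## Matching rules

Tokens are maximal `[A-Za-z0-9]+` runs, so hyphenated compounds split
("drug-abuse" yields "abuse"). Sentences split on `.`, `!`, `?`, `;` and
newline, with guards for decimal points and common abbreviations (Dr., Mr.,
etc.); `;` is treated as a boundary because clinical lists routinely switch
subject at semicolons ("brother uses heroin; pt uses cocaine").

Per-term rules, where the bare term list underdetermines behaviour:

- **prefix-token** matching for abuse, addict, sober, jail, homeless, so
  "abused", "addiction", "sobriety", "jailed", "homelessness" match;
- **exact-token** matching everywhere else; in particular "tox" does not
  match "toxicity" (chemotherapy-toxicity false positives) and "depressed"
  does not match "depression" (which saturates questionnaire boilerplate);
- **"AA" is case-exact** with exclusion cues {amino, acid, african,
  american}: the abbreviation is a strong Alcoholics Anonymous marker but
  collides with amino-acid laboratory text and African-American demographic
  text;
- **"stamps" requires "food"** within 2 preceding tokens, a precision guard
  against postage.

The domain assignment of each term is an implementer choice (the four-domain
partition above); "abuse" is filed under substance use though clinical text
sometimes uses it for child or elder abuse.

## The four false-positive filters

Naive matching in EHR text fails in four recurring ways; each gets one
filter. Order is template → polysemy → negation → subject (cheapest and most
global first); the first filter to fire assigns the mention's status, and
filters never change a mention's term, span, or count — only its status.

| filter | fires when | default parameters |
|---|---|---|
| template | mention's line matches a boilerplate marker, or the identical stripped line recurs in ≥ K distinct notes | markers: checkbox glyphs, screen/questionnaire/PHQ/form/checklist, "denies all of the following"; K = 5 |
| polysemy | any exclusion cue of the term's rule occurs in the sentence | cues per rule (only "aa" has them by default) |
| negation | a trigger occurs within W tokens before the term, same sentence | triggers: no, not, denies, denied, without, never, "negative for"; W = 5 |
| subject | a non-patient cue occurs within W tokens before the term | cues: son, daughter, mother, father, brother, sister, husband, wife, friend, family, partner, neighbor; W = 5 |

Negation looks only backwards; post-negated checkbox formats ("depressed:
no") are in practice template lines and are handled by that filter. Word
markers use word-boundary regexes so "information" or "performed" never
trigger the "form" marker. All lists, windows and the enabled-filter set are
configurable (`FilterConfig`), and disabling any filter can only increase
the number of affirmed mentions (suppression is monotone) — a property the
test suite asserts.

## Statistics

- Quartiles use linear interpolation between order statistics (numpy's
  default, the "type 7" convention). The convention matters only at small n;
  it is documented here because cohort IQRs feed the selection rule.
- **IQR-nonoverlap selection**: a candidate term is retained iff
  [Q1, Q3] of its per-patient occurrence counts in the index cohort and the
  control cohort are disjoint, with touching endpoints counted as overlap
  (the conservative reading). Selection uses raw per-patient occurrence
  counts; classification uses distinct-term counts.
- Contingency metrics with zero denominators are reported as NaN with a
  RuntimeWarning, never silently as 0.
- `threshold_sweep` (metrics at every cutoff 1..22) is a convenience
  extension for tuning, not part of the screening procedure.

## The synthetic corpus generator

No deposited corpus of psychosocially annotated notes exists, so the
generator builds one with an exact gold standard. Defaults encode the study
design the screener assumes: 60 index patients carrying 9–22 distinct true
terms (uniform) and 72 controls carrying 0–8, each true term occurring 1–5
times spread over 3–6 notes per patient, and each of the four confounders
emitted per note with probability 0.1 (false-positive modes are documented
as infrequent; the benchmark utilities raise the rates to stress the
filters). Carrier sentences are short clinical-style templates with a random
visit number per line — the number keeps true-mention lines from colliding
with the template filter's line-repetition test.

Design guarantees:

- every emitted mention (true or confounder) is recorded exactly once in the
  gold standard, and the generator re-scans each note with the real matcher
  to verify that no stray lexicon match slipped into carrier text;
- confounder payload terms are drawn from outside the patient's true term
  set, so with filters off they inflate the distinct-term count (the
  false-positive pressure the filters exist to remove); "aa" and "stamps"
  are excluded as payloads because their case/collocate rules would stop the
  matcher from emitting a candidate at all, breaking the mention-level gold
  standard ("AA" is still exercised by the polysemy confounder);
- all randomness flows from one integer seed; identical seeds give
  byte-identical JSONL output.

What the generator does **not** emulate: realistic clinical language,
misspellings, section structure, copy-forward text, date semantics, or
correlated term co-occurrence. Passing tests on synthetic corpora therefore
demonstrate the pipeline's mechanics (matching, suppression, tallying,
selection arithmetic) under the stated generative assumptions — not
performance on real EHR text, which depends on documentation habits the
generator does not model.

## Problem sizes and numerical choices

The shipped tests and acceptance script use 100–200 patients per cohort
(several hundred notes), where the end-to-end properties are already exact:
a clean corpus with disjoint burden ranges yields precision = recall = 1.0,
and 200 patients per group is ample for the selection study's occurrence
IQRs (index 3–6 vs control 0 occurrences for discriminative terms) to be
estimated without sampling artifacts. Ties in matching are impossible by
construction (one mention per rule–token pair); mentions are ordered by
character offset with term id as tie-break for tokens matching multiple
rules. Degenerate inputs are defined: empty notes segment to zero sentences,
empty cohorts raise, undefined metrics are NaN-flagged.

## Known limitations

- The matcher is a minimal reconstruction of a term-indexing engine; no
  claim of equivalence with any proprietary NLP system is made — fidelity is
  at the level of the four documented false-positive scenarios.
- Negation handling is a trigger-window heuristic, not a full scope parser;
  hypothetical and historical contexts ("r/o depression", "h/o heroin use
  20 years ago") are not modelled.
- The published cohort results (91% accuracy, 80% precision, 98% recall on
  132 real patients; cohort means of 14.1/6.0/2.7/2.0 terms) depend on
  protected patient data and cannot be recomputed here; the package verifies
  the self-contained published numbers (the 22-term list, the ≥ 9 rule, the
  F-measure implied by the printed precision/recall) and the algorithm's
  behavioural properties on synthetic data.
- The ≥ 9 threshold is a property of the 22-term lexicon it was derived
  with; users substituting their own lexicon should re-derive a threshold
  (e.g. with `threshold_sweep`) rather than reuse 9.
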