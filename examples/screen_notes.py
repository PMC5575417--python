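"""Screen a handful of clinical notes and print per-patient classifications.

Builds three small free-text notes in memory, runs the full pipeline
(22-term lexicon match -> context filters -> distinct-term tally -> >=9
positivity rule) and prints each patient's distinct-term count, the terms
found, and the screening call.
"""

from psychscreen import ClinicalNote, screen_corpus, tallies_to_frame

notes = [
    ClinicalNote("alice", "visit-1",
                 "Pt reports heroin and cocaine use. Currently homeless, "
                 "staying in a shelter. Reports anxiety, feeling sad and "
                 "angry. Attends AA. History of substance abuse and prison."),
    ClinicalNote("bob", "visit-1",
                 "Denies cocaine use. Her son is in jail.\n"
                 "PHQ-9 depressed screen: [ ] yes [x] no"),
    ClinicalNote("carol", "visit-1",
                 "Routine follow up, no acute concerns."),
]

result = screen_corpus(notes)
frame = tallies_to_frame(list(result.tallies.values()), result.predictions)
print(frame.to_string(index=False))

# alice has 11 distinct affirmed terms -> positive (>= 9 rule).
# bob's three candidate mentions are all suppressed (negated cocaine,
# misallocated jail, templated depressed) -> 0 distinct terms, negative.
# carol has no lexicon mentions at all -> negative.
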