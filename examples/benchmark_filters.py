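"""Quantify what the false-positive filters buy on a synthetic corpus.

Generates a 60-index / 72-control corpus with each confounder (negation,
template, subject, polysemy) injected in 30% of notes, screens it with the
context filters on and off, and prints both contingency reports. Precision
with filters off drops because confounder mentions inflate control patients'
distinct-term counts past the positivity threshold; filters restore it
without costing recall.
"""

import json

from psychscreen import GeneratorConfig, benchmark_pipeline

cfg = GeneratorConfig(negation_rate=0.3, template_rate=0.3, subject_rate=0.3,
                      polysemy_rate=0.3, seed=11)
reports = benchmark_pipeline(cfg)
print(json.dumps({k: v.to_dict() for k, v in reports.items()}, indent=2))

on, off = reports["filters_on"], reports["filters_off"]
print(f"\nfilters on : precision {on.precision:.2f}, recall {on.recall:.2f}")
print(f"filters off: precision {off.precision:.2f}, recall {off.recall:.2f}")
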