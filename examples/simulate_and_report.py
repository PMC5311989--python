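"""Generate a synthetic cohort and run the full evaluation pipeline.

A 1,790-patient cohort (10x the emulated study, same composition) is
generated, a subset is pushed end-to-end through the interview engine,
and the severity-stratified performance report is assembled.
"""

import pandas as pd

from mddtool import (
    GeneratorConfig,
    default_bank,
    generate_cohort,
    make_report,
    respond_to_interview,
    run_interview,
)

cfg = GeneratorConfig(n=1790)
cohort = generate_cohort(cfg, seed=0)
bank = default_bank()

# end-to-end check on the first 50 patients: scripted answers through the
# interview engine must reproduce the generator's stored detection outcome
clock = lambda: ""
agree = sum(
    run_interview(bank, respond_to_interview(p, bank), now=clock)[1].mdd_positive
    == p.detected
    for p in cohort.patients[:50]
)
print(f"interview round-trip agreement: {agree}/50")

bdi_items = pd.DataFrame(
    [{"respondent_id": p.respondent_id}
     | {f"item_{j + 1}": p.bdi_items[j] for j in range(21)}
     for p in cohort.patients]
)
report = make_report(cohort.table, bdi_items=bdi_items, seed=0, timestamp=False)
print(report.to_markdown())
# Sensitivity rises with severity (mild < moderate < severe) while
# specificity stays constant — severe depression is easiest to detect in
# a structured interview; the reliability block reports the BDI alpha.
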