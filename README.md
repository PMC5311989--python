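# mddtool

A text-mode structured-interview engine for screening **major depressive
disorder (MDD)** against the DSM-5 criteria, with the full statistical
toolkit used to validate such a screener against a clinician's
diagnosis, and a synthetic patient-cohort simulator so the entire
pipeline runs and is testable without clinical data.

It is aimed at researchers evaluating automated diagnostic interviews
(conversational agents, chatbots, computerized screeners) who need a
reproducible interview/classification core and study-style
diagnostic-accuracy reporting.

## What it computes

**Decision rule.** A completed interview resolves the DSM-5 elements of
a major depressive episode: nine A-symptoms `A1..A9`, a two-week
duration gate, functional impairment (B), and exclusions
(substance/medical C, psychotic D, manic E). The screen is positive iff

    #{Ai present} ≥ 5,  including A1 (depressed mood) or A2 (anhedonia),
    duration and impairment met, no exclusion triggered.

**Diagnostic accuracy.** From paired index-test / reference-standard
diagnoses: the confusion table (TP, FN, FP, TN), sensitivity
`TP/(TP+FN)`, specificity `TN/(FP+TN)`, predictive values, exact
Clopper–Pearson 95% CIs, and the single-operating-point ROC area
`AUC = (Se + Sp)/2` with Hanley–McNeil inference — plus a
severity-stratified analysis over BDI-II score bands.

**Questionnaires.** BDI-II scoring (21 items, 0–63, severity bands
0–13 / 14–19 / 20–28 / 29–63), AES acceptability scoring (6 items,
6–30), and Cronbach's alpha `α = k/(k−1)(1 − Σs²ᵢ/s²_total)`.

**Simulation.** Cohorts with configurable prevalence, case-severity
mixture, severity-dependent detection, and correlated BDI-II item
responses; generated answer streams replay through the interview engine
to exactly the sampled outcome. Defaults emulate a 179-patient
sleep-clinic validation cohort (19.6% MDD; case mix 40/34.3/25.7%
mild/moderate/severe; detection 0.21/0.57/0.73 by severity; false-alarm
10/144; BDI alpha ≈ 0.89). See `docs/methods.md`.

## Worked example

```python
from mddtool import ConfusionTable, performance, default_bank, run_interview

# a validation cohort: 179 patients, 35 clinician-diagnosed MDD,
# the automated interview found 17 and raised 10 false alarms
perf = performance(ConfusionTable(tp=17, fn=18, fp=10, tn=134))
print(perf.sensitivity.as_percent, perf.sensitivity.ci_percent)
print(perf.specificity.as_percent, perf.specificity.ci_percent)
print(round(perf.auc.value, 2))
```

prints

```
49 (31, 66)
93 (88, 97)
0.71
```

i.e. the screener catches about half of the true cases (sensitivity 49%,
95% CI 31–66), rarely mislabels healthy patients (specificity 93%,
88–97), and sits well above the chance diagonal (AUC 0.71). Running an
interview is just as direct:

```python
bank = default_bank()                       # 15 DSM-5 questions
transcript, diagnosis = run_interview(bank, ["no", "no"])
print(diagnosis.mdd_positive, len(transcript.entries))   # False 2
```

— a respondent denying both core symptoms screens out after two
questions (the early-exit rule; provably outcome-equivalent to asking
everything).

The `examples/` scripts walk through each capability: interview replay,
questionnaire scoring and reliability, evaluating study counts, and the
simulate → interview → evaluate round trip. A thin CLI wraps the same
functions:

```bash
mddtool simulate --n 400 --seed 5 --out cohort/
mddtool evaluate --in cohort/cohort.csv --out report.json
mddtool interview            # interactive
```

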