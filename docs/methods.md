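# Methods

`mddtool` re-implements, in text mode, the diagnostic core of a
conversational-agent system for screening major depressive disorder
(MDD), together with the statistics used to validate such a screener
against a clinician's diagnosis, and a synthetic cohort generator that
makes the whole pipeline testable without clinical data. This note
records the models, the calibrated defaults, and the design choices
behind them.

## The diagnostic decision rule

The interview engine administers one question per DSM-5 element of a
major depressive episode and classifies the completed transcript with a
deterministic rule. Writing `A1..A9` for the nine criterion-A symptoms
(A1 depressed mood, A2 anhedonia, A3 appetite/weight change, A4 sleep
disturbance, A5 psychomotor change, A6 fatigue, A7 worthlessness/guilt,
A8 concentration, A9 suicidal ideation), the screen is positive iff

```
#{Ai present} >= 5  AND  (A1 present OR A2 present)
AND duration >= 2 weeks  AND  impairment (criterion B)
AND no exclusion triggered (C substance/medical, D psychotic, E manic)
```

Over the 512 possible symptom patterns with the gates satisfied, exactly
227 qualify: `C(9,>=5) − C(7,>=5) = 256 − 29`, where the subtrahend
counts patterns reaching five symptoms without either core symptom. This
enumeration is the independent oracle the classifier is tested against.

Criterion fields are ternary (present / absent / unasked). `classify_mdd`
evaluates the rule under the most and least favourable resolution of
every unasked field and answers only when both agree; otherwise it
raises, so a skipped question can never silently decide a diagnosis.

## The question bank and the early-exit rule

The bundled bank has 15 nodes: A1–A9, the duration gate, the impairment
gate, and four exclusion screens. Criterion C is split into a substance
screen and a general-medical screen — its two clinical halves — which
both feed the single criterion-C profile field (either suffices to
trigger the exclusion). Exclusion screens are phrased so that "yes" is
the favourable answer (`present_if: "no"` in the bank schema), which
keeps a uniformly affirmative respondent internally consistent. Banks
are JSON/YAML documents validated for unique ids, known criteria,
complete branch rules, no dangling targets and acyclicity, so any
drop-in bank terminates on every response stream. A reduced bank
(A-symptoms + duration + impairment, 11 nodes) ships for sensitivity
analyses of the exclusion screens.

Branching policy: questions follow the fixed order A1→A9→DUR→B→C→D→E
unless the bank's branch rules say otherwise. The one dynamic rule lives
in the engine, not the bank: when both core symptoms are denied, no
remaining answer can produce a positive, and the interview terminates
(early exit, on by default, `early_exit=False` to disable). Static
per-node branch rules cannot express a condition on two answers, which
is why this is an engine policy. Its safety is not assumed: the test
suite enumerates all 2^15 full response assignments and checks that the
early-exit diagnosis equals the ask-everything diagnosis.

## Questionnaire scoring and reliability

BDI-II: 21 items scored 0–3, total 0–63, severity bands 0–13 minimal,
14–19 mild, 20–28 moderate, 29–63 severe (boundaries inclusive). AES
(acceptability): six 1–5 Likert items, total 6–30. One published source
describes the AES range as 0–30; this package follows the instrument's
definition (sum of six 1–5 items, so 6–30 — a six-item scale cannot
total below 6). Missing items are rejected, never imputed.

Cronbach's alpha uses `α = k/(k−1)·(1 − Σ s²ᵢ / s²_total)` with sample
variances (n−1 denominator) for items and totals alike — the convention
of mainstream statistical packages; the implementation is cross-checked
in the tests against an independent one (pingouin).

## Diagnostic-accuracy statistics

Sensitivity, specificity, PPV and NPV are binomial proportions; their
95% intervals are exact Clopper–Pearson, computed from beta quantiles
and cross-checked against both a bisection inversion of the binomial
tails and statsmodels. Exact intervals were chosen because they
reproduce, at integer-percent rounding, all eight printed brackets of
the validation table the package emulates. A metric with an empty
denominator is returned as explicitly undefined, never as zero.

A single-threshold classifier has a one-point ROC curve, so
`AUC = (sensitivity + specificity)/2` (trapezoid through (0,0),
(1−spec, sens), (1,1)). Interval and the test against 0.5 use the
Hanley–McNeil standard-error approximation with a normal quantile; for
a single operating point, resampling-based alternatives (DeLong) are
degenerate, and small-sample exactness is not claimed. On the emulated
study table this yields AUC 0.71, CI [0.60, 0.81], p < 0.001; published
software can differ by ±0.01 in the lower bound depending on its SE
convention.

Display rounding is half-up (never banker's): integer percents for
proportions, two decimals for AUC, p-values at three decimals with a
`<0.001` floor. Raw proportions are always carried alongside.

Stratified analysis: per severity stratum of the BDI-II total,
sensitivity is computed over the reference-positive patients whose score
falls in the stratum. The specificity denominator is, by default, the
full reference-negative pool shared across strata — reference-negatives
have no meaningful severity stratum of their own; restricting them to
the stratum's score band is available via `restrict_negatives=True`,
since published stratified tables are ambiguous about this denominator.
With a shared pool, stratified specificity is constant by construction
(≈ 1 − false-alarm rate, here ≈ 93%); the discriminating signal across
strata is sensitivity.

## The synthetic cohort generator

The generator reproduces the statistical structure of a validation
cohort; its defaults are the conditions of the emulated study.

**Composition.** Default `composition="fixed"`: exactly
`round(n · prevalence)` cases, with severity counts apportioned by
largest remainder — at n=179, prevalence 0.196 and mixture
(0.40, 0.343, 0.257) this realises exactly 35 cases split 14/12/9, the
composition of the cohort being emulated. A validation study analyses
one realised cohort, so emulating its fixed composition (rather than
re-drawing it binomially per seed) is the faithful choice; it also keeps
cohort-level statistics from being dominated by case-count noise.
`composition="bernoulli"` gives the independent-draw alternative.

**Detection.** Each case fires the interview classifier with its
severity's detection probability (defaults 0.21 / 0.57 / 0.73 for
mild / moderate / severe); each control fires with the false-alarm rate
(default 10/144 ≈ 0.069). These defaults are calibration choices read
off the emulated study's performance tables, not mechanistic claims.
The implied overall sensitivity is Σ mixᵢ·detectᵢ ≈ 0.467.

**Symptom profiles.** Given the fired/quiet outcome, the patient's
9-symptom pattern is drawn uniformly from the 227 qualifying or 285
non-qualifying patterns respectively, with duration/impairment met and
exclusions clear. Uniform-within-class is the minimal assumption: the
study conditions specify outcome rates, not a symptom-level error
process. By construction, replaying the patient's answers through the
interview engine reproduces the sampled outcome exactly — a cross-module
identity the tests assert at n = 1,000.

**BDI-II items.** Items follow a discretised one-factor model: latent
item `x = m_g + s·(√ρ·F + √(1−ρ)·ε)` with `F, ε ~ N(0,1)`, observed item
`clip(round(x), 0, 3)`. Per group g the location `m_g` is calibrated by
root-finding so the *discretised* mean hits the group target — controls
7.8/21 per item; cases use the case distribution N(22.3, 6.9²) truncated
to the severity class's BDI band (class means ≈ 16.7 / 23.8 / 32.7,
mixture mean ≈ 23.3). Defaults `s = 0.65` and `ρ = 0.08` were tuned once
so the whole-cohort alpha at n=179 centres on 0.89 (the reliability the
generator is calibrated to); across seeds it stays within roughly
[0.86, 0.92]. Because the reported BDI total is the noisy item sum, a
case's observed total can fall outside its latent class band — as real
questionnaire totals do — which slightly blurs stratified sensitivities
toward each other without breaking their ordering.

**AES items.** Same item machinery on the 1–5 scale, calibrated to a
cohort mean of 25.4 with inter-item correlation 0.28 (consistent with an
alpha near 0.7 for six items). A total SD of 4.6 is arithmetically
unreachable for six 1–5 items at that mean under weak dependence; the
realised SD ≈ 3.2. AES output feeds only the scoring pipeline.

**Randomness.** One master seed; reference status/severity/detection,
symptom patterns, BDI items and AES items each consume an independently
spawned child stream, so cohorts are bitwise-reproducible per seed.

### What the generator does and does not emulate

It reproduces: prevalence and severity composition, severity-dependent
detection, the qualitative severity gradient of sensitivity with
constant specificity, group BDI means, and BDI internal consistency. It
does not model: item-level symptom psychometrics (patterns are uniform
within class), comorbidity of a sleep-clinic population, interview-order
or learning effects, correlation between acceptability and symptoms, or
any longitudinal structure. Consequently, passing pipeline tests shows
the software reproduces its configured statistical structure — not that
the screener would achieve these operating characteristics on real
patients.

## Problem sizes and numerical details

The test suite and the acceptance script use: exhaustive enumeration at
512 patterns × 8 gate settings and 2^15 = 32,768 full interview
assignments; rate recovery on a 100,000-patient cohort (binomial SE on
sensitivity ≈ 0.4 points at ~19,600 cases, comfortably inside the ±1
point check); the engine round-trip identity at n = 1,000; reliability
calibration at the study size n = 179 over 20 seeds. Root-finding for
item locations uses Brent's method to 1e-10 on an analytic mean
function (a sum of normal survival functions), so calibration is
deterministic. Degenerate inputs are defined behaviour: zero latent item
SD yields identical item vectors; zero prevalence yields a cohort with
undefined sensitivity and specificity ≈ 1 − false-alarm; empty metric
denominators are flagged undefined.

## Known limitations

- The decision rule operates on one binary answer per DSM-5 element; it
  does not model within-criterion subtleties (e.g. weight change vs
  appetite change as separate probes) beyond the two criterion-C screens.
- Hanley–McNeil inference for a one-point AUC is an approximation with
  no exact small-sample guarantee.
- The stratified specificity convention (shared negative pool) is one of
  several defensible readings of published stratified tables; the
  restricted-denominator alternative is provided but no claim is made
  that either matches any particular publication's convention.
- Generated BDI item vectors have exchangeable items (single factor, no
  item-difficulty profile), which is sufficient for total-score and
  reliability behaviour but not for item-level factor analysis.
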