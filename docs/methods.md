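# Methods

This note documents the models, conventions and design choices behind
`sleepprompt`, in the order the data flow: diary → titration → prompts →
instruments → trial design → analysis → simulation.

## Sleep-diary arithmetic

Clock times are integer minutes since midnight in [0, 1440); dates anchor
entries but intervals are resolved purely from the clocks with one wrap
rule: if the final arising clock (final awakening + bed-out latency) is at
or before the bed clock, the night is taken to cross midnight and 1440
minutes are added. Time in bed therefore always lies in (0, 1440); a
zero-length interval is rejected outright because sleep efficiency divides
by it. Total sleep time is the exact integer identity
`TIB − SOL − WASO − bed-out latency`, and a diary whose latencies exceed its
time in bed is invalid — fields are never imputed or clipped on ingest.
Sleep efficiency is kept at full precision internally and rounded to one
decimal only in presentation tables. Naps and daytime-sleepiness times are
recorded and exposed to the prompt rules but never enter TIB/TST/SE.

A diary week is usable for titration when at least **3** of its 7 days are
present (`MIN_ADHERENT_ENTRIES`). The source program did not quantify
this; three days balances robustness of the weekly mean against discarding
too many weeks, and a non-adherent week simply carries the previous
schedule forward.

## Sleep-restriction titration

The recommended bedtime is `desired wake − (prior week's mean TST + 30 min)`
modulo 24 h. The weekly adjustment of prescribed time in bed is +15 / 0 /
−15 minutes for mean SE > 90 %, in [85, 90] %, and < 85 % respectively —
both band edges hold the schedule, matching the strict-inequality outer
bands. Two safety rails are the package's own conventions (the program
description is silent): a **floor of 300 min** (5 h, the usual
sleep-restriction minimum) that *clamps* low prescriptions, and a **cap of
600 min** (10 h) that *rejects* degenerate inputs such as a reported mean
TST near 24 h — a clamp there would silently launder bad data. The ±15
adjustment moves the bedtime; the wake time is treated as user-anchored.
The SE that drives titration is the diary-derived weekly mean, not the
schedule-implied value. Week numbering: titration produces schedules for
weeks 2–4 only.

## Prompt engine

Messages carry a category, topic, delivery slots, priority and a firing
condition in a small declarative predicate language (field / comparator /
value plus `all`/`any`/`not`), serialized as JSON inside the catalog CSV —
no code execution. Comparisons against state the participant cannot yet
answer (e.g. diary-derived fields before any diary exists) evaluate to
false, keeping every predicate total. Phase gating: hygiene, diary feedback
and praise run weeks 1–4; stimulus control and restriction weeks 2–4.

Scheduling conventions (the program description leaves these open):

* slot anchors — after waking = last arising + 30 min (default 07:30),
  around noon = 12:00, evening = 18:00, before bedtime = set bedtime − 60
  min (default 22:30);
* anchors are moved into the nearest receptive window (circular-distance
  nearest edge); with no windows the anchor is used as-is;
* at most one message per slot (daily cap 4), same-day duplicates excluded;
* a message is not repeated within a 7-day cool-down;
* selection is deterministic: highest rule priority, then least recently
  sent, then lowest message id — so a replayed state stream is
  bit-identical across runs;
* praise triggers at a 3-consecutive-day diary streak ("consistent"
  recording was never quantified at the source).

The shipped seed catalog (40 messages) is representative, not the
clinician-authored production bank, which was never published; the schema
and engine are the reproducible substance.

## Instruments

ISI: 7 items, 0–4 each, total 0–28; insomnia caseness at ≥8 and
randomization strata <8 / 8–14 / ≥15, all cutoffs inclusive as stated.
CFS: 11 items Likert 0–3; global 0–33 with physical (items 1–7) and
psychological (items 8–11) subscales; the bimodal scoring variant is
deliberately not implemented. HPQ: relative presenteeism = B11/B9 clipped
to [0.25, 2.0] (undefined when B9 = 0, reported missing); absolute
presenteeism = 10 × B11. The questionnaire's prose attaches the 1–2-year
label to the absolute formula while citing code B11; this package follows
the item code (the 4-week self-rating), the standard convention. Caffeine:
95/55/45 mg per cup of coffee/tea/cola. BMI obesity at ≥25 kg/m², inclusive.
PHQ-9 screening: exclusion at total ≥10 or item 9 ≥2 ("more than half the
days" on the standard 0–3 anchors). Missing items are never prorated — an
incomplete response is invalid.

## Trial design

Randomization pre-generates, per stratum, a stream of randomly permuted
AABB blocks (block size 4, ratio 1:1) from a generator keyed by (seed,
stratum index), assigning by arrival order. Consequences verified by test:
arm counts equalize after every complete block; imbalance is bounded by 2
per stratum with a partial block; the allocation is reproducible under the
seed, invariant to participant relabeling, and one stratum's stream is
unaffected by enrollment in another.

Sample size uses the two-sample normal-approximation formula
`n = ceil(2 (z₁₋α/₂ + z_power)² σ²/δ²)` rather than the t-corrected
iteration, because the normal form is what reproduces the conventional
planning numbers for a 1.3-point effect with SD 2.3 (50/group, 120 enrolled
after multiplicative 20 % attrition inflation). The chi-square is Pearson's
without continuity correction for all table sizes including 2×2 — the form
that matches the published baseline statistics (6.81, 3.90, 5.85 on the
packaged tables). One known discrepancy: the total-population
alcohol-as-sleep-aid table (1/59 vs 6/50) yields 4.18 by this formula, not
the published 4.22; no correction or alternative statistic we know of
recovers 4.22 from those counts, so the packaged value is simply what the
formula gives. The change-score comparison is the pooled-variance
independent-samples t test; with zero pooled variance it degenerates and
the implementation reports p = 1 for a zero difference and p = 0 otherwise
(n < 2 or non-finite input raises instead).

## Longitudinal analysis

The primary model is a linear mixed model with a random intercept per
participant and fixed effects for week (continuous 0–4), arm, and
week × arm, estimated by REML with two-sided Wald tests; the interaction —
the between-arm difference in weekly ISI slope — is the primary estimate.
Missing weeks are absent rows, never imputed. Baseline is modeled as the
week-0 response, not a covariate, consistent with analyzing five time
points. Continuous-linear time is the primary coding; a categorical-time
variant (`time_coding="categorical"`, interaction reported at the week-4
contrast) is provided for sensitivity. With noise-free data the fixed
effects are recovered to numerical precision (≤1e-8 in tests).

## Synthetic cohort

The simulator emulates the study conditions, not any participant's data.
Weekly ISI follows a linear-trend random-intercept model
`isi = b_i + week·(decline + arm·extra) + e`, rounded and truncated to
integers in [0, 28] — so the analysis model is correctly specified by
default, and parameter-recovery checks isolate the estimator. Defaults,
chosen once as the study conditions: 58 per arm (≈ the analyzed size of
the motivating trial), baseline mean 9.2 with intercept SD 2.0 and residual
SD 2.5, control decline −0.3 points/week and extra intervention decline
−0.3 points/week — the endpoint calibration that carries group means from
9.2/9.2 to ≈6.8/8.0 over four weeks (a calibration, not a reproduction of
any outcome). Week 0 is the screening measurement itself and also feeds
stratification.

Diaries: bedtime ≈ 23:30 (SD 40 min) and wake ≈ 06:45 (SD 25 min) with
±15/±10-min nightly jitter, lognormal SOL (median ≈ 20 min), normal WASO
(20 ± 15 min, truncated), 10 % missing days, and app-install dropout at
2/62 in the intervention arm only. Intervention participants run the real
titration engine on their accumulating diary; their waking overhead shrinks
by `titration_response` (default 1) SE percentage point per active
restriction week, emulating consolidation. Latencies are bounded by
construction (SOL, WASO ≤ TIB/3; bed-out ≤ TIB/6) so every generated entry
passes strict diary validation. Pre-post secondary outcomes (CFS scales,
presenteeism) are drawn around plausible worker-population levels with
small arm-specific changes.

All randomness derives from one user seed through named substreams
(cohort, randomization, ISI, diaries, secondary, dropout), making every
export byte-identical under the same (config, seed).

What the simulator does **not** model: floor effects and skew in ISI
(beyond truncation), circadian physiology, weekday/weekend structure,
adherence that depends on symptom severity, or learning effects in
questionnaires. Passing calibration tests therefore shows the estimator and
engine behave correctly under the stated generating model, not that the
intervention works on real data.

## Verification sizes

The Monte-Carlo checks in `tests/test_acceptance.py` use 500 replicates at
the default conditions for parameter recovery (mean interaction within
±0.05 of the injected −0.3) and 1000 replicates under the null
(`extra_decline_spa = 0`) for the interaction test's type-I error
(5 % ± 2 points at α = .05). Large-sample calibration checks (trajectory
means, dropout rate, law-of-large-numbers on the baseline) use 4000–5000
participants per arm without diaries.

## Known limitations

* The prompt rule language covers comparisons and boolean combinators only;
  rules over free-form history (e.g. trends) require derived state fields.
* Receptive windows are assumed not to cross midnight.
* `ModelFit` exposes Wald inference only; no Kenward-Roger or profile
  likelihood small-sample corrections.
* The chi-square requires strictly positive marginals; sparse tables are
  the caller's responsibility (no exact test fallback).
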