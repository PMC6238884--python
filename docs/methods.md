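# Methods

This note documents the model behind `diakb`, its tunable parameters, the
numerical conventions, what the synthetic data generator does and does not
emulate, and the design decisions taken where more than one reasonable
choice existed.

## The reasoning model

The module is a classical hypothesize-and-test expert system.  A
*knowledge base* declares hypotheses (claims about the data or the
patient's physiology), organizes them into ordered *plans* of
problem-identifying tasks, attaches *activation rules* (which context each
task needs), *evaluation rules* (which registered operation tests the
claim) and *explanation templates* (how a validated claim is phrased for
the reader).  The *engine* generates a plan case from the root plan,
activates each pending hypothesis — flagging it **NA** with the name of the
missing context when its activation rule fails — evaluates it, stores the
result, and lets stored results update the plan case: a validated event
detection appends that event's cause sub-plan, scoped to the event.  The
run ends at a fixpoint.  Because the trigger graph of the shipped knowledge
base is acyclic (detections trigger cause trees, cause trees trigger
nothing), the fixpoint is reached after at most one sub-plan per event; a
hard iteration cap proportional to hypotheses × registrations guards
against malformed knowledge bases and is never reached on well-formed ones.
An evaluation fault is converted to an NA result with justification
"evaluation failure" — a consultation must degrade, not abort.

Hypothesis instances are *scoped*: reliability hypotheses to the whole
dataset, cause hypotheses to one noticeable event, the sleep hypothesis to
one night.  The per-event instancing generalizes the per-night wording of
the sleep rule, which is the only explicitly instanced case in the source
material.

Three combination semantics exist:

- **default-TRUE parents** ("there was not enough insulin", "too many
  carbohydrates", "too much insulin", "too few carbohydrates", "physical
  activity preceded the event"): the branch is assumed and the engine tries
  to invalidate it; it becomes FALSE exactly when *every* child is FALSE or
  NA, i.e. it stays TRUE when at least one child validates;
- **lack of evidence**: TRUE exactly when no sibling branch is TRUE — the
  definition of an *information gap*, the situation where the module
  invites the user to investigate the data around the event;
- **leaves**: evaluated directly by a registered rule.

## Event detection

Blood-glucose readings are classified before thresholding.  *Fasting* is
inferred as "no carbohydrate registration in the preceding 8 h" — the
source rules leave the inference open ("if the information is available"),
and a carbohydrate-free 8 h window is a conservative, configurable proxy.
*Before-meal* means a carbohydrate intake classed as a meal follows the
reading within the 30-minute insulin-meal window.  Fasting and before-meal
readings use the 9.0 mmol/L hyperglycemia bound; before-meal hypoglycemia
is judged at the non-fasting 3.5 mmol/L bound (only fasting is given a
separate hypoglycemia bound).  All threshold comparisons are strict.

A *single continuous event* is a maximal run of consecutive out-of-range
readings with no in-range reading between them, split when it would exceed
the 6 h maximum duration; the reference time is the extreme reading of the
run.  The 6 h cap is stated for hyperglycemia and applied to hypoglycemia
by symmetry (configurable).  Blood-pressure events are per reading
(systolic > 140 **or** diastolic > 90, pairing systolic/diastolic rows that
share a timestamp).  The sleep rule considers, for each night (20:00 to
12:00 the next day), the gap between the consecutive *manual* registrations
that brackets 03:00; sensor-automatic rows are ignored, a night with no
bracketing pair is NA, and a gap under 7 h is an event.

## Cause rules and fallback chains

- Required correction dose = (BG at reference − 5.5 mmol/L) / ISF.  ISF
  falls back from the patient-reported value to the 1500/1800 rule applied
  to the mean total daily dose (bolus + basal, the classical usage; the
  1800/500 numerators are used because bolus registrations are treated as
  rapid-acting).
- I:C falls back from reported → same-day totals (total carbohydrates over
  total rapid-acting insulin) → the 500/450 rule.  The source-consistency
  check, by contrast, always compares the reported value against the
  500/450-rule value, so that it tests the patient's report against an
  independent derivation.
- IOB uses linear decay with configurable insulin action duration (default
  4 h); an optional bilinear curve (triangular activity peaking at 75 min)
  sits behind the same contract — remaining fraction 1 at injection, 0 at
  DIA, monotone between.  Only the contract matters to the rules.  COB is
  linear absorption at the patient-reported rate and is NA without one.
- "Average active insulin" is the mean of IOB sampled on a 5-minute grid
  over the whole diary period (the averaging window is not pinned by the
  source material; the whole period was chosen and is flagged for review in
  a clinical pilot).  The grid average of a piecewise-linear function with
  jump discontinuities at bolus times converges at first order, which is
  ample for a comparison of averages.
- The hypoglycemia child "active insulin greater than required per I:C" is
  operationalized as IOB at the reference exceeding (carbohydrates in the
  4 h window) / I:C; the "last injection too high" child judges the last
  dose against the requirement implied by the most recent BG reading at or
  before the injection (what the patient could have known), floored at 0.
- Activity intensity: an explicit tag wins; otherwise a quantity strictly
  below 60 min / 3000 steps / 6 METs is light-to-moderate and anything at
  or above the bound is treated as extreme.  Light-to-moderate activity is
  sought within 4 h of a hypoglycemic event, extreme activity within 24 h;
  absence of any activity within 24 h is the hyperglycemia activity cause.
- External factors (menstruation, polypharmacy, sickness) are flagged when
  any external-factor registration falls on the calendar day of the event.
- Every cause branch's activation requires its data type to be present in
  the context at all; otherwise the branch and its children are NA.  This
  is what routes a data-poor event to "lack of evidence" rather than to a
  spurious cause, and it makes result degradation monotone: removing a data
  type moves the affected hypotheses to NA instead of flipping them.

## Data reliability and trust

Trust starts at 50 and each validated reliability sub-hypothesis deducts
its grade, clamped at 0.  Only the 10-point HbA1c deduction is anchored in
the source guidance; the remaining weights (5 for each missing type, 10 for
each error-value family, 5 for the count and distribution checks, 10 for
each reported-parameter inconsistency) are module defaults surfaced in
`ThresholdConfig.grades`.  Details per family:

- *Plausibility ranges*: blood glucose [1.1, 33.3] mmol/L — the lower bound
  is physiologic (values beneath it are near-certain registration errors);
  carbohydrates (0, 300] g and insulin (0, 100] U are module decisions.
  A type with no registrations is NA here (absence is the missing-type
  hypothesis' finding).
- *Counts*: at least 5 blood-glucose registrations per day (the only
  source-anchored minimum); insulin 1/day for insulin users, carbohydrates
  1/day, activity 0/day by default.  Only types present in the diary are
  judged.
- *Distribution*: the dispersion statistic is the population standard
  deviation of per-day (or per-weekday-total) counts, flagged when it
  exceeds 20% of the mean; an alternative max-absolute-deviation statistic
  is selectable in configuration.  Days with zero registrations enter the
  dispersion like any other day.
- *Source consistency*: relative deviation |calculated − reference| /
  reference above 5% flags the HbA1c (vs laboratory), ISF and I:C (vs
  patient-reported) checks; either side missing gives NA.

The numeric trust grade is exposed in the JSON output only; rendered
reports state the concrete problems instead, because a bare number proved
meaningless to readers.

## Numerical conventions

Canonical units are mmol/L, U, g, mmHg; mg/dL inputs are divided by 18.016
at the I/O boundary.  Timestamps are timezone-naive local clock time at
minute resolution.  Windows are half-open on the old side (end-inclusive),
so a registration exactly N hours before an event is excluded — one
convention everywhere.  Duplicate (timestamp, type, source) rows collapse
to one with a logged warning, since device re-syncs produce them.  Strict
threshold comparisons use an exact-tie guard (relative 1e-9): a deviation
constructed to sit exactly on a printed tolerance compares as equal, not
greater, so the boundary semantics survive floating-point round-off.

## Synthetic data

`ScenarioSpec`/`generate` produce a diary from a baseline-plus-meal-
excursion glucose model with Gaussian noise (defaults: baseline 6.0 mmol/L,
excursion +2.0 mmol/L within 3 h after a meal, noise SD 0.3), three meals
(40/60/60 g) with fixed boluses (4/6/6 U), a nightly 20 U basal dose and a
daily 30-minute walk, over 14 days starting on a Monday so every weekday
occurs twice and the distribution checks are structurally satisfiable.
These defaults are chosen so that the anomaly-free diary is *fully
compliant*: trust 50, zero events, zero findings — the baseline every
anomaly-recovery test compares against.  Eight anomaly kinds can be
injected (missed bolus, fabricated smoothing, missing day, wrong unit,
extreme value, hypo/hyper injection, conflicting reported ISF), each with a
declared target hypothesis and a ground-truth log.

The generator is **not** a physiological simulator: no insulin-glucose
dynamics, no circadian variation, no sensor error model.  Passing tests
demonstrate that the rules respond correctly to data with the stated
structure, not that the thresholds are clinically optimal, and real diaries
— irregular, multi-source, gappy — will exercise the NA paths far more than
the synthetic ones do.

## Problem sizes

The test suite and the acceptance script run on deliberately small inputs:
flip-point sweeps use single-day to 14-day diaries (10–101 diaries per
sweep), the engine-versus-brute-force equivalence check uses 1000 seeded
two-day contexts with at most two injected events, and property tests use
a few dozen examples each.  These sizes fully determine the discrete
thresholds being recovered; larger diaries change nothing but runtime.

## Known limitations

- One printed claim in the source narrative (a validated hyperglycemia
  "adds 18 hypotheses") is not reconstructible from the enumerated tree,
  which yields 11 nodes (5 branches + 4 + 2 children); the knowledge base
  encodes the enumerated tree.
- Completed results are never retracted by plan updates; a context shift
  mid-run is out of scope.
- Basal insulin is modelled only through daily totals (TDD), not as a
  continuous background infusion; pump temp-basals are out of scope.
- The sleep rule measures registration gaps, not sleep; a night owl who
  simply stops registering looks identical to a short sleeper.
- Patient-defined glycemic target ranges are deliberately not consumed:
  they would override the medical standards the event definitions encode.
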