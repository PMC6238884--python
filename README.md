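# diakb

Knowledge-based reasoning over self-collected type 1 diabetes diaries.

Patients with type 1 diabetes accumulate large volumes of self-collected
health data — finger-prick glucose, bolus and basal insulin, carbohydrate
intakes, physical activity, blood pressure — that clinicians rarely use,
partly because its reliability is unknown and partly because extracting the
relevant episodes takes longer than a consultation allows.  `diakb`
implements a context-aware, hypothesize-and-test expert system for exactly
this setting.  Given a diary, a patient profile and optionally a laboratory
HbA1c, it:

1. **grades data reliability** on a 0–50 trust scale (50 = full trust) by
   testing sub-hypotheses for missing data types, implausible values, too
   few registrations, uneven distribution over days and weekdays, and
   inconsistencies between the module's own calculations and independent
   references;
2. **detects noticeable medical events**: continuous hyperglycemic episodes
   (BG > 9 mmol/L fasting/before meals, > 13.9 mmol/L otherwise),
   hypoglycemic episodes (BG < 4 mmol/L fasting, < 3.5 mmol/L otherwise),
   high blood pressure (> 140/90 mmHg) and short nights (< 7 h between
   manual registrations);
3. **evaluates a causal hypothesis tree per event** — insulin-related causes
   (insulin on board below/above average, last dose vs the dose the insulin
   sensitivity factor prescribes for reaching 5.5 mmol/L, the
   insulin-to-carbohydrate ratio, forgotten meal boluses), carbohydrate
   causes (carbs on board, intake size vs meal/snack recommendations),
   external factors, and physical activity — and flags an **information
   gap** when every candidate cause is refuted or not applicable;
4. **renders** hedged findings, recommendations and event summaries as
   JSON, Markdown or HTML.

The medical arithmetic uses the standard clinical approximations: the
Nathan linear HbA1c ↔ estimated-average-glucose relation
(`eAG [mg/dL] = 28.7·A1C − 46.7`), the 1500/1800 rule for insulin
sensitivity (`ISF = 1800/TDD` mg/dL per U for rapid-acting insulin), the
500/450 rule for the carb ratio (`I:C = 500/TDD` g per U), and linear
insulin-on-board / carbs-on-board decay models.

A hypothesis resolves to TRUE, FALSE or **NA** (not applicable) when its
required context is missing — NA is first-class: the engine never guesses,
and the reliability report tells the patient which data to start
registering.  The knowledge base (hypotheses, plans, activation and
evaluation rules, explanation templates) is declarative data that
round-trips through YAML, so extending the rule set is an edit, not a code
change.  All test inputs come from a seeded synthetic diary generator with
injectable anomalies (forgotten boluses, unit mistakes, fabricated values,
missing days, conflicting reported parameters); no external data is needed.

## Worked example

```bash
diakb generate --fixture hypo_activity --out diary.csv --profile-out profile.json
diakb analyze diary.csv --profile profile.json
```

prints

```
# Consultation report

## Data reliability

- **Data reliability: too few registrations per day.**
  - days below the registration minimum: 2024-03-04: 2 blood_glucose (minimum 5)
  - Registering more often (at least 5 blood glucose measurements a day) lets the module compute reliable trends.

## Noticeable events

### event:hypoglycemia:2024-03-04T15:00

- This hypoglycemic event may have been due to the fact that there were too few carbohydrates.
  - *No carbohydrate intake was registered in the 4 h before the event.*
- This hypoglycemic event may have been due to the fact that physical activity preceded the event.
  - *1 light-to-moderate activity registration(s) in the 4 h before the event.*

## Summary

- hypoglycemic events: 1
- events possibly caused by `hypo_physical_activity`: 1
- events possibly caused by `hypo_too_few_carbohydrates`: 1
- hypoglycemia distribution: per hour [15h×1]; per weekday [Mon×1]
```

Reading it: the diary holds one day with a blood glucose of 3.0 mmol/L at
15:00 — below the 3.5 mmol/L non-fasting bound, hence a hypoglycemic event.
Two cause branches validate: no carbohydrates were registered in the 4 h
before the event, and a 2500-step walk (light-to-moderate, i.e. under 3000
steps) preceded it within 4 h.  Only two glucose measurements were taken
that day, under the five-per-day minimum, so the reliability section asks
for more frequent registration.  The numeric trust grade is kept out of the
rendered report by design (`--format json` exposes it for API consumers).

The same pipeline is available as a library:

```python
from diakb import build_context, default_kb, run, golden_fixtures

kb = default_kb()
fx = golden_fixtures()["hba1c_mismatch"]
ctx = build_context(fx.registrations, fx.profile, fx.lab, kb.config)
result = run(ctx, kb)
print(result.trust.trust_level)   # 40: the HbA1c inconsistency costs 10 points
```

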