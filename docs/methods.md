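# Methods

## The validation problem

GP-coded pneumonia in COPD patients cannot be validated directly against
clinical truth: primary care rarely has chest radiography, and the data
contain no negative labels. The pipeline therefore estimates two one-sided
accuracy measures against the hospital record:

* **PPV of GP coding**, computable only for GP events severe enough to be
  admitted: among GP-coded pneumonia events followed by an admission within
  7 days, the share whose hospital gold-standard diagnosis is pneumonia.
* **Sensitivity of GP recording** of hospitalised pneumonia: among hospital
  admissions with a pneumonia gold diagnosis, the share receiving a GP
  pneumonia code within 42 days of admission.

Neither specificity nor NPV is estimable (false negatives are unobserved);
they are deliberately out of scope.

## Definitions and conventions

**Gold standard.** The primary (position-1) ICD-10 code of the *last*
consultant episode of a spell; pneumonia is the J12–J18 family. The last
episode is the one with the highest episode-order value, ties broken by the
latest episode start, an unresolvable tie being an error. Using the last
rather than the first episode avoids the non-specific symptom codes often
attached to the first episode of an admission. The alternative
`any_position_last_episode` mode classifies the spell as pneumonia when any
diagnosis of the last episode is J12–J18, falling back to the primary code's
category otherwise — by construction it can only reclassify *toward*
pneumonia, so the any-position PPV dominates the primary-mode PPV on every
dataset.

**Five-category classification** of a hospital primary diagnosis, applied
as ordered prefix rules so it is total and mutually exclusive: J12–J18 →
pneumonia; configured COPD families (default J40–J44) → COPD; any other
chapter-J prefix → other respiratory; chapter I → circulatory; anything
else → other. ICD-10 codes are normalised by uppercasing and stripping dots.

**Candidate events.** GP pneumonia codes of one patient separated by at
most 14 days (chained) collapse into a single event indexed at the earliest
code; the gap is configurable, since repeat-coding behaviour is
practice-specific. Events must fall inside the patient's follow-up window.
Two filters then apply to the PPV arm only: *prospective coding*
(observation date equals data-entry date, so that hospital letters recorded
back into the GP system after the fact are not mistaken for GP diagnoses),
and *community onset*.

**Community onset (hospital-acquired exclusion).** An event is excluded
when its index date lies inside a spell that began *before* the index date,
or within 14 days after such a spell's discharge. An admission on or after
the index date never excludes the event: it is the consequence of the GP
diagnosis, not its source. This choice is forced by the same-day analysis —
a rule excluding any index date inside any spell would empty the
denominator of the same-day-admission sensitivity analysis, which the study
design explicitly keeps.

**Linkage horizons.** All intervals are closed. PPV linkage takes the
earliest admission in [index, index + 7 days] (day 0 allowed; date ties
broken by spell identifier). Recording looks in [admission, admission + 42
days], anchored on admission rather than discharge so that long stays are
not penalised. In the recording stage no entry-date restriction applies:
retrospective recording still counts as recording, and no hospital-acquired
exclusion applies because every hospitalised pneumonia ought to reach the
GP record regardless of onset.

**The 19 algorithms.** Row 1 is the pneumonia code alone; the others add
components that must occur within a symmetric ±7-day window of the index
date: symptoms (codes from ≥2 *distinct* categories of new cough, sputum,
breathlessness, fever, lethargy, tachycardia — repeated codes from one
category do not qualify), chest X-ray referral, culture sent / culture
positive, and antibiotics. Two antibiotic modes exist: any issue, or an
issue with a recorded course length of 5–14 days; combination rows use the
any-duration mode. Course length comes from an explicit duration field —
no dose/quantity inference is attempted. The window is symmetric because
the direction of the component relative to the code is not constrained by
the design; it is configurable for users who prefer an anchored window.

**Estimation.** Every reported figure is a binomial proportion with a 95%
Clopper–Pearson interval computed through the beta-quantile representation
of the binomial tails (a Wald option exists for comparison with normal-
approximation outputs; published one-decimal intervals in this literature
are sometimes only reproducible under the approximation). Percentages are
rounded half-up to one decimal — the convention of clinical tables, where
banker's rounding would flip boundary cases. Rendered tables censor counts
of 1–4 as "< 5"; machine-readable reports keep exact counts, and censoring
is applied only at rendering.

**Cohort.** Eligibility: COPD diagnosis at age ≥ 35 (completed years from
exact dates), registration overlapping any part of 2015–2019, linkage
eligibility. Follow-up runs from max(study start, COPD diagnosis + 1 year,
registration start) to min(study end, death, transfer-out, last collection
date). "+1 year" means same month and day the following year, with Feb 29
mapping to Mar 1. Exclusion stages are applied in a fixed order (COPD
diagnosis → age → registration → linkage → follow-up time) so flow counts
are deterministic and non-increasing. The data model carries no separate
internal-quality flag; schema validation on read plays that role.

## The synthetic generator

`synthetic_data.generate` emulates what the licensed extract provides: a
registry with configurable fractions of ineligible patients (too young, not
linkage-eligible, dead before the study) for flow testing; true pneumonia
episodes arising as a Poisson process inside each follow-up window; GP
presentation, miscoding (an AECOPD/LRTI code is emitted instead — visible
in the data, invisible to the pneumonia pipeline, mirroring the
disjointness of the two codelists); same-day versus retrospective entry;
admission within 0–7 days; hospital confirmation of the last-episode
primary diagnosis; and hospital-only pneumonia admissions recorded back to
the GP within 0–42 days, optionally with a same-day hospitalisation code.
Spells carry 1–3 episodes with the gold code in the last episode, and
unconfirmed spells can carry a secondary-position pneumonia code to
exercise the any-position mode. Offsets are drawn uniformly over their full
horizons so boundary days occur with positive probability.

Episodes within a patient are spaced at least 70 days apart. This is the
load-bearing trick that turns the ground truth into an *equality* oracle:
the maximal forward reach of one event's records is 49 days (7-day
admission offset + 42-day recording offset), and 49 + the 14-day
deduplication gap is still under 70, so no generated record can chain,
flag, or link across neighbouring events. `realized_rates` recounts the
intended outcomes, and the pipeline must reproduce them *exactly* on every
seed — a far sharper test than statistical agreement.

Default parameters are the study conditions where the study states them:
admission probability 0.277, confirmation probability 0.577, non-pneumonia
category mixture 0.320/0.129/0.123/0.428, recording probability 0.341,
same-day hospitalisation-code share 0.595 of recordings, secondary-position
pneumonia probability 0.23 (the value implied by the gap between the
any-position and primary-mode PPVs). Where the study is silent, values were
chosen once for realism: a true-episode rate of 0.04/patient-year with 50%
GP presentation and 33% pneumonia-coding probability (reproducing the
observed GP-coded event rate of roughly 0.007/patient-year), 80% same-day
entry, a hospital-only pneumonia admission rate of 0.028/patient-year, and
component emission rates that reproduce the observed orders of magnitude of
X-ray referral, symptom, antibiotic and culture coding, slightly separated
by confirmation status so the algorithm grid shows realistic PPV contrasts.

What the generator does **not** emulate: comorbidity and prescribing
covariate structure, seasonality, practice-level clustering, correlated
confirmation and admission-delay processes (confirmation is independent of
the admission offset, so the same-day-restriction analysis does not raise
the PPV here as it does in real data), and miscoded episodes never lead to
admissions. Passing tests therefore demonstrate the *correctness of the
pipeline's counting and interval logic* under the study's date semantics,
not the clinical realism of any particular estimate.

## Problem sizes used by the checks

The equality suite runs 20 seeds at 2,000 patients; the calibration study
uses replicates of ~2,000 linked events (the size at which a 95% interval
has ±2.2% width) with 200 seeds in the test suite and 100 in the
acceptance script; the full-pipeline acceptance run uses 100,000 patients,
giving roughly 575 linked events and 11,000 hospital pneumonia events —
enough for sub-percentage-point Monte-Carlo error on the sensitivity and
~2% on the PPV. These sizes are the package's own trade-off between
resolution and runtime.

## Numerical and degenerate-input choices

* k = 0 and k = n interval bounds are set exactly to 0 and 1 (no quantile
  call); zero denominators yield an undefined estimate rendered as a
  censored row rather than an error.
* Rounding of percentages and interval bounds is decimal half-up at one
  decimal, applied after the interval computation.
* Date parsing is strict ISO-8601; a bad value reports its file line.
  Referential integrity (orphan patient identifiers), duplicate
  spell/episode/position keys, inverted spell dates and episodes outside
  their spell are hard errors, not warnings.
* Linkage ties (two admissions the same day) resolve by spell identifier;
  event clustering is order-independent and idempotent.

## Known limitations

* The shipped codelists are synthetic structural stand-ins (real UK
  terminologies are licensed); users with real extracts must supply their
  own lists in the same CSV shape.
* The PPV is conditional on hospitalisation and is best read as an upper
  bound for milder disease; nothing here estimates specificity or NPV.
* Whether multiple qualifying events per patient should count separately is
  configurable in spirit (each spell/event counts once here); patient-level
  first-event analysis can be obtained by pre-filtering the event table.
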