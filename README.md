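# pneumolink

Validation of pneumonia coding in linked primary/secondary-care electronic
health records for COPD populations.

Diagnosing pneumonia in a patient with chronic obstructive pulmonary disease
(COPD) is hard: the symptoms overlap with an acute exacerbation of COPD
(AECOPD), and the chest X-ray needed for a definitive diagnosis is usually
only available in hospital. Epidemiological studies that define pneumonia
outcomes from GP-recorded codes therefore risk serious misclassification.
`pneumolink` implements, as a tested and reusable pipeline, the two-stage
validation of GP pneumonia coding against the hospital record:

1. **Positive predictive value (PPV)** of primary-care pneumonia coding.
   Candidate events are clusters of GP pneumonia codes that were entered on
   the day of observation (prospective coding) and did not arise during or
   shortly after a hospital stay. Events followed by a hospital admission
   within 7 days are compared against the gold standard — the primary
   (position-1) ICD-10 diagnosis of the admission's *last* consultant
   episode, pneumonia being J12–J18:

   PPV = (linked events with gold diagnosis J12–J18) / (linked events).

   Nineteen identification algorithms combine the pneumonia code with
   supporting components recorded within ±7 days: ≥2 distinct symptom
   categories (new cough, sputum, breathlessness, fever, lethargy,
   tachycardia), chest X-ray referral, antibiotics (any duration or a 5–14
   day course), sputum/blood culture sent, and culture-positive results.
   Sensitivity analyses allow a pneumonia code in *any* diagnosis position
   of the last episode, and restrict to same-day admissions.

2. **Sensitivity of GP recording** of hospitalised pneumonia. Hospital
   admissions with a primary last-episode diagnosis of J12–J18 inside a
   patient's follow-up period are checked for a GP pneumonia code within 42
   days of *admission* — alone, or paired with a same-day generic or
   respiratory hospitalisation code:

   sensitivity = (hospital pneumonia events recorded in time) / (all such events).

All proportions carry exact (Clopper–Pearson) 95% binomial intervals,
obtained by inverting the binomial tails; rendered tables suppress counts of
1–4 as "< 5".

Because the real data sources (CPRD Aurum primary care linked with Hospital
Episode Statistics admitted patient care) are licensed, the package ships a
**synthetic linked-EHR generator** that reproduces their relational
structure — registry, dated observations with separate entry dates,
prescriptions, spells made of ordered episodes with ordered ICD-10 lists —
and the relevant error structure: GP miscoding of pneumonia as AECOPD/LRTI,
retrospective data entry, and incomplete GP recording of hospitalisations.
Every generated dataset comes with exact ground truth, so the pipeline is
tested by *equality* against an independent recount, not by approximation.

## Worked example

```python
from pneumolink.synthetic_data import paper_like_config, generate
from pneumolink.cli_report import run_pipeline

dataset, truth = generate(paper_like_config(seed=7, n_patients=20000))
result = run_pipeline(dataset)
row = next(r for r in result.report.rows
           if r.algorithm_id == 1
           and r.gold_mode == "primary_last_episode"
           and not r.same_day_only)
print("cohort patients:", result.stage_counts["cohort_patients"])
print("eligible events:", row.events)
print("admitted within 7 days:", row.admitted)
print("PPV:", row.estimate.render())
sens = result.sensitivity["code_only"]
print("hospital pneumonia events:", result.sens_n)
print("sensitivity:", sens.render())
```

prints

```
cohort patients: 18041
eligible events: 415
admitted within 7 days: 114
PPV: 57.9 (48.3-67.1)
hospital pneumonia events: 2125
sensitivity: 34.2 (32.1-36.2)
```

Of 20,000 simulated COPD patients, 18,041 meet the eligibility criteria
(aged ≥ 35 at diagnosis, registered during 2015–2019, linkage-eligible, with
follow-up time after one year of COPD diagnosis). They yield 415 prospective,
community-onset GP pneumonia events, of which 114 are admitted within 7
days; 57.9% (95% CI 48.3–67.1) of those admissions carry a pneumonia gold
diagnosis — close to the preset confirmation probability of 0.577. Of 2,125
hospital pneumonia events, 34.2% are recorded by the GP within 42 days
(preset recording probability 0.341).

The same pipeline runs from the shell:

```bash
pneumolink simulate --out data/ --seed 7 --n-patients 20000
pneumolink run-all --out results/ --seed 7 --n-patients 20000
```

writing `flow_counts.csv`, `table2.csv` (the 19-algorithm grid under both
gold-standard modes and same-day variants, censored), a non-pneumonia
diagnosis breakdown, `sensitivity.csv` and an uncensored `report.json`.

## Layout

| module | role |
| --- | --- |
| `pneumolink.ehr_model` | domain types and strict CSV readers/writers for the four tables |
| `pneumolink.codelists` | codelist loading/matching, ICD-10 five-category classification |
| `pneumolink.cohort` | eligibility, follow-up windows, flow accounting |
| `pneumolink.algorithm_engine` | candidate events, filters, the 19 component algorithms |
| `pneumolink.validation` | linkage, gold-standard classification, PPV and sensitivity |
| `pneumolink.stats` | exact binomial intervals, half-up rounding, small-cell censoring |
| `pneumolink.synthetic_data` | ground-truth generator and exact recount oracle |
| `pneumolink.cli_report` | pipeline runner, report writer, typer CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
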