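# idda

Tools for the **IDDA2.1 "kaleidoscope" score** — the immune deficiency and
dysregulation activity score used to quantify disease activity in patients
with inborn errors of immunity (IEI), in particular primary immune
regulatory disorders (PIRDs) with autoimmunity, inflammation and
lymphoproliferation. It is aimed at immunology clinicians, registry
curators and methodologists who need a reproducible implementation of the
score, of its cohort-level radar ("kaleidoscope") profiles, and of the
phenotype-matrix clustering used to compare diseases.

## The score

A visit is documented on 22 items. Fourteen organ/feature items (lines
1–14: autoimmune cytopenia, hemophagocytosis/HLH, enteropathy/IBD,
lymphoproliferation, parenchymal lung disease, skin/eye, granuloma,
endocrinopathy, arthritis, AI-hepatitis, nephropathy, neurologic
involvement, failure to thrive, severe infections) are graded 0–4
(0 absent … 4 life-threatening/refractory). With the Karnofsky/Lansky
performance scale *k* (line 15), non-ICU hospital days *h* and ICU days
*u* out of the last 100 days (lines 16–17), and supportive-care items
(lines 18–21: immunoglobulin substitution scored 0/2/3, chronic
infestation, other organ dysfunction, nutrition status, each 0–4), the
per-visit total is

```
total = ( Σ lines 1–14  +  H(h)  +  U(u)  +  Σ lines 18–21 ) × M(k)

H(h) = 0.1·h  if h < 40,  else 4
U(u) = 0.8·u  if u < 10,  else 8
M(k) = 150/k  if k > 29,  else 6
```

All three branch conditions are strict. The attainable range is 0 to
(56 + 4 + 8 + 15) × 6 = **498**. Malignancy (line 22) is noted but never
adds points.

The **kaleidoscope function** reduces 17 of the 22 items (lines 1–14,
then 20, 18, 22, in that fixed order) to presence/absence and plots, per
cohort, the percentage of patients with each feature on a 17-axis radar
chart. Stacking several diseases' frequency vectors gives a phenotype
matrix that is clustered hierarchically (complete linkage, Euclidean
distances, after a logit transform truncated at 1%) and drawn as a
red-high / blue-low heatmap with marginal dendrograms.

Because single-patient data behind published multi-disease cohorts are
not publicly deposited, the package includes a seedable synthetic-cohort
generator (`idda.synthetic`) whose disease archetypes produce cohorts
with planted feature-frequency profiles, so the whole pipeline is
testable end to end.

## Worked example

```python
from idda import VisitRecord, compute_score

rec = VisitRecord(
    patient_id="LRBA-07",
    visit_date="2021-03-01",
    organ_grades=(4, 3, 2, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0),
    performance_scale=70,          # Karnofsky 70%
    hospital_days_per_100=20,      # 20 of the last 100 days in hospital
    icu_days_per_100=0,
    igg_substitution="iv",         # regular IVIG -> 3 points
    chronic_infestation=2,
    other_organ_dysfunction=1,
    nutrition_status=2,
)
b = compute_score(rec)
print(b)
```

prints

```
ScoreBreakdown(organ_sum=13, hosp_term=2.0, icu_term=0.0, supportive_sum=8,
               multiplier=2.142857142857143, total=49.285714285714285,
               malignancy_flag=False)
```

i.e. organ grades sum to 13, the 20 hospital days add 2.0, supportive
care adds 3 + 2 + 1 + 2 = 8, and the subtotal 23 is multiplied by
150/70 ≈ 2.14 for a total of **49.29**. A fully healthy visit scores 0;
the worst possible visit scores 498.

## Command line

```bash
idda simulate --n 50 --cohorts 8 --seed 42 --out visits.csv   # synthetic study
idda validate visits.csv                                      # rubric findings
idda score visits.csv --out scores.csv                        # per-visit breakdowns
idda trajectory visits.csv --patient tregopathy-C1-P0001      # longitudinal series
idda kaleidoscope visits.csv --groups visits.csv.truth.tsv \
     --group-by cohort --out-dir plots/                       # radar charts + TSV
idda cluster plots/frequencies.tsv --out heatmap.svg \
     --tree-out diseases.nwk                                  # clustered heatmap
```

`idda simulate` writes a truth-label sidecar TSV so recovered clusters can
be compared against the planted archetypes.

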