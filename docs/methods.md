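# Methods

This note documents the models and procedures implemented in `idda`, the
parameters that matter, the numerical choices made where the published
description leaves room, and what the synthetic-data tests do and do not
demonstrate.

## The per-visit score

The IDDA2.1 total is a product of an additive burden subtotal and a
performance-scale multiplier:

```
total = (organ_sum + hosp_term + icu_term + supportive_sum) * multiplier
```

* `organ_sum` — sum of the fourteen organ/feature grades (lines 1–14),
  each an integer 0–4; range 0–56.
* `hosp_term` — `0.1 × days` for non-ICU hospital days out of the last
  100, capped at 4 points from 40 days on. Both branches give 4 at
  exactly 40 days, so the term is continuous; the branch condition is
  strict (`< 40`), matching the published spreadsheet expression.
* `icu_term` — `0.8 × days` for ICU/ventilation days, capped at 8 from
  10 days on; continuous at the boundary, strict `< 10`.
* `supportive_sum` — immunoglobulin substitution (0 none / 2 sporadic /
  3 regular IV or SC) plus lines 19–21, each 0–4; range 0–15.
* `multiplier` — `150 / k` for performance scale `k > 29` (1.5 at 100%,
  5.0 at 30%), fixed at 6 for `k ≤ 29`. This floor is a genuine
  discontinuity: the multiplier jumps from 5.0 at 30% to 6 at 29%. It
  exists to correct for very low performance values, which would
  otherwise blow the quotient up without bound.

The attainable range is 0–498, with 498 reached only when every
component is at its maximum. Malignancy (line 22) is carried on the
breakdown as a flag and never enters the arithmetic. All arithmetic is
double precision; user-facing CSV output stores full-precision `repr`
values so round trips are lossless, and display rounding is left to the
consumer.

### Validation and missing data

Validation returns findings (data), one per violated rubric rule, each
naming the offending item line; it never raises. Choices where the
rubric is silent:

* Performance values are accepted at any integer 10–100; non-decile
  values produce a *warning* finding, not an error, because the formula
  divides by the raw value while Karnofsky/Lansky are conventionally
  decile-stepped. Values below 10 are rejected.
* Hospital/ICU days may be fractional (they are rates over a 100-day
  observation window) and must jointly fit in the window
  (`hosp + icu ≤ 100`).
* Lines 1–14 and 19–21 may be marked missing (`None`), which is distinct
  from grade 0. Scoring refuses such records by default
  (`missing_policy="refuse"`); explicit missing-as-zero imputation is
  available and yields a lower bound on the true total.

### Longitudinal operations

`score_trajectory` sorts one patient's visits by date (duplicate dates
and mixed patient ids are errors) and is therefore invariant to input
order. Trend labels compare consecutive totals strictly: all
non-increasing with at least one decrease → `improving`; the mirror case
→ `worsening`; all equal → `stable`; otherwise `mixed`. The convention
is ours — no published rule exists. `phase_delta` compares two therapy
phases by per-item means (line 18 on its points scale, line 22 as 0/1),
excluding missing values from each mean, plus the difference of mean
totals.

## Kaleidoscope profiles

The cohort view keeps 17 of the 22 items — lines 1–14, then 20, 18, 22,
in that fixed order — and reduces each to presence/absence: grade ≥ 1
for graded items (any non-zero grade is the minimal faithful reading of
"qualitative information"), any substitution for line 18, the flag for
line 22. Lines 15–17 (percentages), 19 (dominated by asymptomatic
infestation) and 21 are not axes.

Frequencies are per-axis: `100 × present / assessed`, where the
denominator counts patients with the item assessed. Axes nobody had
assessed are *unavailable*, rendered as gaps in the radar polygon and
empty cells in the TSV — not as zeros, which would fabricate absence.
Aggregation is patient-level: the caller passes one representative
record per patient, either the latest visit (default) or a worst-ever
synthesis (per-item maxima across visits), since cohort summaries
assembled from case series usually report lifetime phenotype. Both
policies are exposed because published aggregations do not state which
was used.

## Phenotype clustering

A diseases × 17 matrix of presence proportions is transformed with a
truncated logit: proportions clamped to `[eps, 1 − eps]` with
`eps = 0.01` ("truncated at 1%"), then `ln(q/(1−q))`. The natural log is
our choice; the base is a global monotone scale factor, so it changes
distances by a constant factor and leaves both dendrogram topologies and
leaf orders unchanged. Rows (diseases) and columns (features) are then
clustered independently: agglomerative, complete linkage, Euclidean
distances — via `scipy.cluster.hierarchy.linkage`, which the tests check
against a naive O(n³) agglomerator written directly from the definition.
Complete linkage guarantees monotone merge heights, so exported Newick
branch lengths (differences of merge heights) are non-negative.

Numerical choices:

* Exact distance ties are resolved by SciPy's deterministic ordering;
  output is reproducible for a given input. Ties have measure zero for
  logit-transformed empirical frequencies.
* Unavailable axes are imputed at the clamp floor 0.01 with a warning —
  the least-informative finite coordinate, chosen so imputation cannot
  dominate a distance. Small cohorts (n < 10) make frequencies
  unreliable; that is a disclosure for the reader, not a filtering rule.
* The transformed values are clustered unscaled by default; optional
  row/column z-scoring is exposed (`scale="rows"|"cols"`) because
  heatmap tools differ in their defaults.
* The heatmap colors the transformed values on a diverging red-high /
  blue-low palette centered at logit 0.5 = 0.

## Synthetic cohorts

The generator exists because the multi-disease cohort tables behind
published kaleidoscope galleries are aggregate numbers without deposited
single-patient data. An `ArchetypeSpec` holds 17 presence probabilities
(one per axis; the last two drive immunoglobulin substitution and
malignancy), a severity distribution over grades 1–4 given presence
(default uniform), performance-scale parameters (`kps_base = 90`,
−4 per present feature, rounded to the nearest decile and clamped to
[10, 100] — decile rounding keeps generated records free of even
warning findings), cohort-mean hospital/ICU day rates, and
distributions for lines 18 (category given substitution), 19 and 21.

Per patient, features are independent Bernoulli draws — deliberately
minimal; real organ involvement is correlated, so passing recovery tests
demonstrates the pipeline separates frequency profiles, not that it
handles realistic covariance. Day counts are truncated normals whose
mean scales with the patient's feature burden relative to the
archetype's expected burden; ICU days are truncated to the remainder of
the 100-day window. All randomness flows from one integer seed
(`numpy.random.default_rng`; per-cohort seeds spawned via
`SeedSequence`), so studies are bit-reproducible.

The three bundled archetypes (a Tregopathy-like, an antibody-deficiency-
like and an EBV-susceptibility-like profile) are illustrative, not
calibrated to any published cohort. They differ by ≥ 0.4 in presence
probability on ≥ 6 of 17 axes — a separation at which the clustering
pipeline recovers the planted assignment (adjusted Rand index ≥ 0.9) in
the bundled study configuration of 8 cohorts per archetype and 50
patients per cohort, a size typical of the case series such analyses
draw on and comfortably fast to simulate.

## Known limitations

* Fidelity to published cohort figures cannot be verified quantitatively:
  the underlying per-patient data are unpublished, so cohort-level tests
  are property-based (oracle agreement, invariances, planted-structure
  recovery) rather than value comparisons.
* No correlation structure between features in the generator; no
  bootstrap support values or ordination on the clustering side; no
  survival analysis; no HPO coding of items.
* The 100-day hospitalization window is taken as given; behavior for
  irregular visit intervals (overlapping or gapped windows) is the
  caller's responsibility.
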