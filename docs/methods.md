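# Methods

## The variable catalogue

The canonical schema fixes 61 variables in six domains with sizes
9/6/13/2/11/20. The intra-group membership is reconstructed from the standard
geriatric patient record:

* **anthropometric (9)** — gender, age, size (height), weight, body-mass
  index, body mass, lean mass, fat mass, total water. The patient-record item
  "drug number" is not duplicated here: polypharmacy is already a geriatric
  syndrome flag, and folding the count into that flag keeps the domain at its
  printed size. Gender and age also appear as instance metadata; as schema
  variables they participate in similarity like any other.
* **functional (6)** — Tinetti gait-and-balance score, Barthel index,
  Lawton & Brody score, Get-Up-and-Go score, a needs-physical-help flag, and
  the five-category independence-in-ADL classification. Treating the ADL
  classification as the sixth functional variable (rather than splitting
  Tinetti into separate gait and balance scores) is the reading that yields
  exactly six.
* **nutritional (13)** — total protein, serum albumin, cholesterol,
  triglycerides, blood iron, ferritin, vitamin B12, serum folic acid, serum
  transferrin, leukocytes, lymphocytes, hemoglobin, calcium.
* **cognitive (2)** — Mini-Mental Status and the "Cruz Roja" mental scale.
* **geriatric syndromes (11)** — binary flags: dementia, depression,
  incontinence, immobility, recurrent falls, polypharmacy, comorbidity,
  sensory deprivation, pressure ulcers, malnutrition, terminal illness.
* **dispersion (20)** — see below.

Chronic-pathology groupings (cardiovascular, neurological, ...) fall outside
these six domains and are not part of the catalogue.

## Kept-value semantics

A later assessment may mark a variable "kept" (`k` in the CSV dialect): not
re-measured, carried forward. Resolution forward-fills from the same
patient's most recent earlier *present* value; a kept marker with no
antecedent resolves to missing. This rule is the one under which the packaged
missingness fixture reproduces its wave totals exactly: 1057 existing values
in wave 1 and 644 in wave 2 (340 freshly measured + 304 carried forward).
The corresponding wave-3 bookkeeping cannot be reconciled with any kept
counting rule we tried (653 present-only, 851 with chained carry-forward),
so the fixture's accounting guarantees target waves 1 and 2 only. A kept
marker in a first-iteration row is rejected at parse time — it has no legal
antecedent.

## Dispersion measures

Seven indicator families are computed from a waist-worn tri-axial
accelerometer signal recorded during a gait exercise. Per axis: arithmetic
mean, sample standard deviation (n−1), absolute mean difference, variance,
amplitude (max − min) and the Pearson coefficient of variation sd/|mean|; for
the magnitude series √(ax²+ay²+az²): its mean ("acceleration mean") and
sample SD. That composition — 6 × 3 per-axis statistics plus 2 magnitude
statistics — is the only one consistent with both the seven named indicators
and the domain size of 20, and is documented here because the source
indicator list is ambiguous about it. Two further interpretation choices:

* *absolute mean difference* is read as the mean absolute deviation about the
  axis mean (not the Gini mean difference, not successive differences) — the
  simplest reading, flagged as an open interpretation;
* the n−1 convention is used for all SDs/variances (small clinical samples),
  fixed so tests can assert exact values.

A zero-mean axis has no defined coefficient of variation; the value is
reported missing for that axis and flagged, never raised as an error (a
constant-zero axis reports 0).

Preprocessing is a centered moving average per axis (odd window, default 5
samples, shrinking at the edges) followed by trimming a fixed duration
(default 1 s) from each end to drop start-up and slow-down artefacts. The
pipeline names these steps (filtering, segmentation) without fixing
operators; these are the simplest deterministic choices and both are
configurable.

## Similarity

The weighted Gower general similarity coefficient is used as defined in
Gower's 1971 form, S_ij = Σ w_k δ_ijk s_ijk / Σ w_k δ_ijk. Numerical
choices:

* quantitative ranges R_k are recomputed from the *current* stack's present
  values (population-relative normalization), never from fixed clinical
  bounds; a zero range scores the variable 1 for every pair;
* binary variables default to symmetric matching — co-absence of a syndrome
  counts as agreement, which is the clinically meaningful reading — with
  Gower's asymmetric dichotomous rule (co-absence not comparable) behind
  `SimilarityConfig(binary_mode="asymmetric")`;
* a pair with Σ w_k δ_ijk = 0 has no defined similarity and raises
  `IncomparablePairError`; matrix cells for such pairs are NaN, never a
  silent 0;
* ranking ties break by ascending instance id, making every ranking and
  every treemap deterministic;
* weight profiles are per-variable in [0, 1]; a group name in a profile file
  is shorthand assigning that weight to every member variable (an importance
  slider for the whole domain), with explicit per-variable entries taking
  precedence. Group weights are *not* divided among members: a domain at
  importance 1 means each of its variables is fully weighted.

Unit normalization precedes any comparison: quantitative cells may carry a
unit tag, converted to the variable's canonical unit through a small
multiplicative registry (g→kg, m→cm, mg/dl→g/dl, ...); an unknown unit is an
error naming the variable.

## Treemap

The root is the studied instance (similarity 1). Children are the top-ranked
neighbors of their parent — ranked against the parent, not the root — with
depth capped at 3 levels and 3 children per node by default; deeper trees
carry ever-lower similarity to the studied patient and stop being readable.
With default caps, exactly four ranked lists are computed per tree: one for
the root and one per second-level child (third-level nodes are leaves).
Candidate lists exclude every node already placed anywhere in the tree
(breadth-first placement), the strictest duplicate-free policy; a
`path_only` mode that excludes only ancestors is available. Same-patient
instances are allowed as candidates by default and can be excluded.

Layout is slice-and-dice with alternating split orientation per level:
siblings tile their parent's rectangle exactly, areas proportional to their
similarity coefficients (equal split when all are zero). Squarified layouts
are out of scope. The SVG fill is a linear interpolation between `#deebf7`
(similarity 0) and `#08519c` (similarity 1); endpoints are fixed so renders
are byte-deterministic.

## Synthetic data

No raw clinical values were ever published for this setting, so the
generators emulate *structure*, *counts* and *demographics* — not clinical
joint distributions. Consequences:

* `generate_cohort` draws per-sex ages from a seeded normal and then
  affinely rescales the draw so the sample mean and SD (n−1) equal the
  configured demographics *exactly* (defaults: 10 men 81.80 ± 4.74, 10 women
  85.43 ± 3.22 years, three assessment waves). This makes the cohort's
  printed statistics deterministic identities rather than expectations. The
  quoted overall mean (83.58) differs slightly from the average of the
  sex-specific means (83.615); the generator matches the sex-specific
  moments. Non-demographic values are uniform within plausible clinical
  ranges (categoricals uniform, syndrome flags Bernoulli 0.35); dispersion
  variables are computed from simulated gait signals rather than drawn, so
  they satisfy the same internal identities as measured ones.
  `quantitative_stage_shifts` plants a known additive per-wave shift on
  anthropometric and nutritional values, the handle used for longitudinal
  parameter-recovery checks.
* `table_pattern_fixture` realises the transcribed per-patient, per-wave,
  per-domain counts of present/kept values (20 patients, waves at instance
  ids 1–20, 22–41 and 47–64, patients 6 and 14 absent from wave 3). Within a
  domain the first *n* variables in schema order are the present ones — the
  transcription records counts, not positions. One transcription ambiguity
  (patient 6's geriatric row showing a dash before a kept marker despite the
  missing third wave) is resolved as wave-2 = kept, wave-3 = absent. Values
  are fixed by a packaged seed; a CSV copy ships in `frailtymap/data/`.
* gait signals are per-axis sinusoids at a step frequency (default 1.7 Hz,
  elderly gait) with amplitudes (1.0, 0.6, 0.4) m/s², a 1 g vertical offset
  and seeded Gaussian noise (default SD 0.3 m/s²).

Passing tests on these fixtures therefore demonstrate correctness of the
*mechanics* (accounting, similarity, ranking, tree structure, recovery of
planted trends), not reproduction of any published similarity percentage —
those depend on the unpublished raw values and are explicitly not a target.

## Evolution analysis

Stages map to assessment waves: initial → 1, spontaneous evolution → 2,
post-supplementation → 3. Stage summaries are arithmetic means over present
values per sex and variable, restricted to the nine-variable nutrition
profile. A mean is suppressed ("no data") when fewer than `min_n` values
contribute; the threshold behind published "no data" cells is unknown, so
`min_n` defaults to 3 and is configurable. Deltas are differences of means
where both exist; trends are sign-based (declined/maintained/improved) with
an optional dead band ε (default 0), and deliberately carry no clinical
direction semantics — whether a lower weight is good depends on context the
tool does not model. Elapsed time between stages is metadata only; the
analysis is not time-weighted.

## Problem sizes and determinism

Everything is deterministic given seeds: cohort generation, gait simulation,
similarity, treemaps (tie-break by id), JSON and SVG bytes. Test and
acceptance workloads use desk-scale sizes — stacks of 14–60 instances,
recordings of a few hundred samples, a few hundred seeded replicates per
property — chosen so the full suite completes in seconds while still
exercising every rule path.

## Known limitations

* The exact intra-domain membership of the 61 variables is a reconstruction;
  the domain sizes, not the member names, are the load-bearing constraint.
* Wave-3 existing-value accounting is not reconcilable (see above).
* No clustering (dendrograms, k-medoids) or sex/age pre-stratification;
  ranking is flat within the stack.
* The unit registry covers common clinical conversions only.
* Synthetic value distributions are uniform and independent across
  variables; real biochemistry is correlated.
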