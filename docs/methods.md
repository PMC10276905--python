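# Methods

## Frequency-based rarity classification

The unit of analysis is the patient, represented by one randomly selected
hospital stay. The adult filter (age ≥ 18 at admission) is applied *before*
stay selection so that minors' stays cannot influence which stay is chosen.
Selection is uniform over each patient's stays, seeded, and performed on
rows sorted by `(patient_id, stay_id)` so the result is independent of
storage order. Diagnosis codes are normalised to the 4-character ICD-10
category+subdivision form — uppercase, dots removed, then clipped to four
characters — and de-duplicated within the stay before any counting: the
frequency definition counts patients, not code mentions.

Code frequencies are computed on the post-selection one-stay-per-patient
cohort. The alternative — counting over all stays — is exposed through the
`frequency_basis` argument of `prepare_analysis_frame`, because counting on
all stays would re-introduce exactly the over-representation that
single-stay selection removes; patients is therefore the default.

Each patient's rarity key is the minimum patient count over their codes
(ties on the key broken lexicographically when naming the rarest code,
which never affects the decile). Patients are partitioned into `q` quantile
groups (deciles by default) by

    decile(k) = clamp(ceil(q · F(k)), 1, q)

where `F(k)` is the proportion of patients with key ≤ k. This rule keeps
tie blocks together — all patients sharing a key share a decile — at the
price of slightly unequal group sizes whenever a tie block straddles a
boundary, which is unavoidable with heavily tied count data (in real data a
large share of patients have a singleton rarest code). Degenerate case: if
every patient shares one key, `F ≡ 1` and all land in the top group.

The FB-RDx flag is `decile ≤ cutoff`; cutoff 1 is the primary definition,
cutoffs 2 and 3 give the 20%/30% sensitivity variants. A `ChapterFilter`
optionally removes codes of ICD-10 chapters XVIII–XXII (symptoms R00–R99,
injuries/external consequences S00–T98, external causes V01–Y98, health-care
contact Z00–Z99, special purposes U00–U99) before rarity scoring; the
minimum over a subset can only rise, so the filter never makes a patient
look rarer. Patients whose codes are all filtered out are dropped from that
sensitivity cohort with a logged count.

Catalog matching is exact on truncated 4-character codes — no prefix or
range semantics, which would silently broaden a catalog's definitions.

## Outcome models

Five outcomes, each with its own analysis population:

| outcome | model | exclusions |
|---|---|---|
| in-hospital death | logistic | none |
| 30-day readmission | logistic | deaths, rehabilitation clinics |
| ICU admission | logistic | rehabilitation clinics |
| log LOS (days) | OLS | deaths, rehabilitation clinics |
| log ICU-LOS (hours) | OLS | deaths, rehabilitation clinics, non-ICU stays |

30-day readmission is `0 < days_to_readmission ≤ 30` among survivors;
a missing readmission delay means no readmission. LOS outcomes are
log-transformed (they are strongly right-skewed), so exponentiated
coefficients are multiplicative effects on the geometric mean; nonpositive
LOS values are a data error, never silently dropped.

Adjusted models include sex, Swiss citizenship, admission from home, age,
the number of non-rare diagnoses, admission type (reference: emergency),
insurance class (reference: mandatory) and hospital category (reference:
tier-1 university hospital). The readmission model additionally adjusts for
log LOS. The number-of-diagnoses covariate excludes the rare codes
themselves — codes whose frequency would place a patient in the flagged
quantile for FB-RDx/decile models, catalog codes for the catalog models —
binned as 0, 1, …, 10, 11–12, 13–15, ≥ 16 with 0 as reference.

Age enters through a restricted cubic spline: linear term plus, for knots
t₁ < … < t_k,

    s_j(x) = [(x−t_j)₊³ − (x−t_{k−1})₊³ (t_k−t_j)/(t_k−t_{k−1})
                        + (x−t_k)₊³ (t_{k−1}−t_j)/(t_k−t_{k−1})] / (t_k−t₁)²

for j = 1..k−2, which is linear beyond the boundary knots with a continuous
second derivative everywhere. Five knots at Harrell's default quantiles
(0.05, 0.275, 0.50, 0.725, 0.95 of the included population's ages) are the
default; 3–7 knots are supported. A categorical age-group adjustment
(18–34, 35–49, 50–64, 65–79, 80+) is available for robustness comparison;
on synthetic data it moves the predictor estimate by well under 10%.

Inference is Wald throughout: `CI = exp(β ± z₀.₉₇₅·SE)`. For a 2×2 table
the Woolf interval (variance = sum of reciprocal cell counts) is provided
and coincides with the covariate-free logistic fit. The decile
dose–response model uses decile 10 (the most-common decile) as reference
and reports one estimate per decile 1–9 plus an OLS trend line through the
point estimates on the ratio scale (unweighted by default,
inverse-variance weights optional — the choice of trend weighting is a
presentation decision, not an inferential one).

### Numerical choices

* Logistic fits use Newton–Raphson; if it fails to converge (it can
  oscillate with sparse cells) the fit restarts with BFGS from the last
  iterate. Perfect separation and singular-Hessian failures are reported
  via `separation`/`converged` flags on the results object, never silently.
* Number-of-diagnoses bins with fewer than 30 patients are merged into the
  neighbouring bin before fitting (lowest surviving bin becomes the
  reference). In a cohort of hundreds of thousands every bin is populated
  and this is a no-op; in desk-scale cohorts it prevents quasi-separation
  from cells with zero events. The rarity predictor's estimate is
  insensitive to this reparameterisation.
* All-zero dummy columns (empty factor levels after exclusions) are
  dropped to keep designs full rank.
* Percentages in reports are rounded half-up to one decimal, matching the
  convention of printed baseline tables.
* Chi-square tests are computed without continuity correction and
  Kruskal–Wallis with tie correction (conventional defaults).

## The synthetic cohort generator

The generator emulates the statistical structure of a national adult
inpatient year, with every parameter exposed in `SimulationConfig`:

* **Code universe** — `n_codes` (default 2000) unique 4-character codes
  with Zipf sampling weights `w_r ∝ r^(−s)`, `s = zipf_exponent = 1.5`.
  The long tail yields many near-singleton codes, which is what makes a
  bottom decile meaningful.
* **Stays** — 25% of patients have ≥ 2 stays (`p_multi_stay`), with
  2 + Poisson(0.62) stays each, giving ≈ 1.4 stays per patient overall.
  A patient's diagnosis set is drawn once — 1 + negative-binomial
  (r = 2.2, mean 11) draws, de-duplicated, clipped to 50 — and repeated on
  each of their stays: readmissions re-document the same condition, the
  very over-representation that motivates single-stay selection.
  The de-duplicated count has median 6 (IQR ≈ 4–9).
* **Demographics / administration** — age uniform on 18–100, 56% female,
  78.5% citizens, 90.4% admitted from home; admission-type, insurance and
  8-level hospital-category draws match typical inpatient marginals.
* **Latent truth** — a patient is *latently rare* when their rarest drawn
  code (by generating-weight rank) lies in the bottom 10% of patients.
  The flag is defined from the generating weights, not from observed
  frequencies, so ground truth is independent of the classifier under
  test. It is returned in a separate truth table; observable tables carry
  no latent columns.
* **Outcomes** — binary outcomes are Bernoulli with
  `logit p = logit(baseline) + ln(rarity_or)·rare + 0.1·(age−59)/10 −
  0.1·female + 0.2·emergency`; baselines 0.020 (death), 0.039
  (readmission), 0.052 (ICU), rarity odds ratio 1.5 each. The small fixed
  covariate effects make adjustment non-trivial without dominating the
  rarity signal. Deaths suppress readmission; LOS is log-normal
  (μ = 1.45, σ = 0.75 → median ≈ 4.3 days) and ICU hours log-normal
  (μ = 3.25, σ = 0.80 → median ≈ 26 h, ICU stays only), both multiplied by
  `rarity_los_multiplier = 1.05` for latently rare patients.
* **Catalog** — codes are selected with probability ∝
  `exp(rarity_bias · rank/n)`; the default bias 3.0 concentrates the
  catalog in the rare tail so catalog prevalence falls from roughly 15–20%
  in decile 1 to 0% in decile 10 while keeping some mid-frequency codes,
  the qualitative pattern seen in real catalog-vs-decile cross-tables.
  Bias 0 selects uniformly.

What the generator does **not** emulate: real ICD-10-GM code semantics,
comorbidity correlation between codes, seasonal or multi-year structure,
hospital-level clustering, or coding-practice variation between hospitals.
Passing tests therefore demonstrate that the pipeline's logic and inference
are correct under a faithful-but-idealised data-generating process, not
that any particular clinical effect size is real.

### Parameter recovery and regression dilution

With the default configuration at 50,000 patients, the adjusted death
model's 95% CI contains the generating odds ratio 1.5 in 19 of 20 seeded
replicates. The replicate-mean point estimate is ≈ 1.41, not 1.50: the
FB-RDx flag is an *estimate* of latent rarity (observed code counts are a
noisy, tied version of the generating-weight ranking, and decile boundaries
fall inside tie blocks), and this exposure misclassification attenuates the
estimate — classical regression dilution. Fitting the same model with the
latent flag itself recovers 1.5 without bias, which separates generator
correctness from classifier noise; both properties are under test. At the
scale of a real national cohort (~830k patients) the count ranking is less
noisy and the dilution correspondingly smaller.

## Problem sizes

The test suite and acceptance script use cohorts of 20,000–50,000 patients
and 20 replicates for the recovery study — sizes at which quantile
boundaries, exclusion rules and sparse-cell handling are all genuinely
exercised while a full run stays comfortably interactive. Published-count
arithmetic (odds ratios, percentages) is exact at any scale.

## Known limitations

* Complete-case analysis only; no multiple imputation or hospital-level
  random effects (out of scope by design).
* Exact 4-character matching may miss catalogs authored at 5-character
  granularity; normalise such catalogs before loading.
* The decile-size imbalance induced by tie blocks means the "10%" groups
  are approximate; with extreme tie structures (e.g. most patients sharing
  one key) lower deciles can be empty, which downstream models surface as
  missing decile terms rather than hiding.
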