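# Methods

This note documents the statistical model behind `organclock`, the
synthetic-data generator's assumptions, the numerical choices, and the
limits of what the test suite can demonstrate.

## Cohort model

Participants are recruited uniformly over a four-year window with
chronological age `A ~ Uniform(37, 73)` at recruitment (var(A) = 108
y²). Sex is Bernoulli (default female fraction 0.544), BMI is
log-normal around 27 kg/m², smoking status is never/previous/current
(0.55/0.35/0.10) with log-normal pack-years for ever-smokers and zero
by definition for never-smokers; ~15% of ever-smokers have pack-years
masked to missing. Raw alcohol frequency has four levels
(low/high/stopped/unreported). Ten ancestry PCs are standard normal.
A configurable fraction (default 0.40) has GP coverage; everyone else
is unobservable in the coded-record stream and ends up with status
`unknown`.

### Latent organ age and biomarkers

Each organ o has a latent biological age `L_o = A + G_o` with gap

    G_o = N(0, gap_sd²) + δ_o·case + γ_o·GRS_sd + λ_p·packyears + λ_b·(BMI − 27)

Defaults: gap_sd = 3 y; case shifts δ mirror the observed pattern of
this analysis class (immune +0.21 y, hepatic −0.25 y, small positive
elsewhere); genetic slopes γ are 0.01–0.03 y/SD with negative signs for
the cardiovascular and pulmonary systems; lifestyle slopes λ are small
and positive. Markers are exchangeable within an organ:
`m_j = intercept_j + l·L_o + N(0, σ²)` with p = 5 markers, loading
l = 1 and σ = 62.5 by default. Missingness is MCAR at 10% (an optional
flag makes it age-dependent for robustness experiments).

**Calibration identity.** With equal loadings the population R² between
one organ's panel and chronological age is

    R² = var(A) / (var(A) + gap_sd² + σ²/(p·l²))

(the generator exposes this as `CohortConfig.oracle_panel_r2()` and its
inverse `with_panel_r2(r2)`). The defaults give R² = 0.120, i.e. a
held-out clock correlation of √0.12 ≈ 0.35 — the weak-clock regime in
which biobank-scale organ clocks actually operate (r ≈ 0.27–0.39).

### Disease, records, decoys

Disease follows a logistic liability, linear in age (0.09/y),
pack-years (0.008/y·pack), BMI (0.02 per kg/m²) and the scaled genetic
score (log OR 0.47 ≈ OR 1.6 per SD); the intercept is solved by Brent's
method so the population probability hits `disease_prevalence_target`.
Every case receives at least one coded record from one of three true
code families (F42, F45, XaI); a configurable fraction of cases is
dated before recruitment (prevalent) or before age 40. Decoy code
families (X00, XaE, 2BB, ...) are assigned to ~1% of participants
independently of liability. Codes identify their family by their first
2–3 characters. For bookkeeping simplicity cases without GP coverage
also receive records; the classifier assigns `unknown` from the
coverage flag, never from record absence, so those records are inert.

The generator does **not** emulate: linkage disequilibrium between
variants, marker-identity realism (panels are exchangeable within an
organ, unlike real 3–35-marker panels), correlated biomarker noise
beyond the shared latent age, informative missingness by default,
competing mortality, or coding-practice drift over calendar time.
Passing tests therefore demonstrate correctness of the machinery under
these idealised conditions, not robustness to the full messiness of
real primary-care data.

## Phenotyping

Records are pooled into code families at prefix lengths 2 and 3;
validation runs at both lengths and a length-3 verdict shadows its
length-2 parent. Each family with ≥ 20 carriers gets one logistic fit
of carrier status on age, sex, pack-years, the CFH-role and ARMS2-role
dosages and the overall scaled genetic score. The retention rule is a
conjunction: the score term must be significant (p < 0.05) with
positive log OR, **and** at least one of age/CFH/ARMS2 must be
significant with risk-increasing sign; both thresholds are
configurable, since the verbal rule this operationalises ("failed to
reach significance with one or more risk factors and had effect sizes
close to zero") does not pin down one conjunction. Families below the
carrier minimum, or with separation, are removed with a flag and no
estimate. Classification precedence is: no GP coverage → `unknown`;
first qualifying event before age 40 → `excluded`; on/before the
recruitment day (day-level comparison, recruitment day counts as
prevalent — the conservative incident definition) → `prevalent`; after
→ `incident`; no qualifying event → `control`.

## Preprocessing

Pack-years: zero for never-smokers; smoking-status-group median for
ever-smokers with missing values. Alcohol: dichotomised at three
drinks/week, stopped drinkers set to missing (sick-quitter concern),
"missing" kept as its own factor level in all association models.

Markers with **strictly more than 20%** missingness are dropped before
imputation (exactly 20% is retained). The rest are completed by
chained equations — Bayesian-ridge conditional models with
posterior-noise draws, 10 sweeps, columns in ascending-missingness
order — producing a single completed dataset. Each organ is imputed in
isolation: only same-organ markers plus four auxiliary covariates
(sex, smoking, BMI, chronological age) enter the conditional models,
so one organ's ageing signal cannot leak into another's imputed
values. The imputation RNG is derived from the master seed plus the
organ label, making organs reproducible independently.

## Clocks

**Split.** Cases and participants with unknown/excluded/prevalent
status never enter the training or test pools. The test set (21.4% of
non-cases, mirroring the source design's 40,240/187,961) is selected
by 1:k nearest-neighbour quota sampling: each incident case claims
~n_test/n_cases of its nearest non-cases in (age, BMI, pack-years)
space, with distances scaled by the per-variable matching tolerance so
age (±0.5 y) dominates the metric; a bounded swap pass then repairs any
residual median offset. This reproduces the stated property — the test
medians match the case medians — directly, rather than any particular
matching package's internals. Matching is without replacement.

**Weights.** w(a) = 1 + |a − ā|/s, capped at 5, normalised to mean 1 —
the simplest positive scheme that is monotone in distance from the
mean age. Because the weight depends on the *response*, weighted least
squares genuinely tilts the fit toward extreme ages and provably
reduces the growth of |residual| with |a − ā| relative to uniform
weights (asserted as an acceptance property). The cap almost never
binds for uniform age distributions (max distance ≈ 1.73 s).

**Backends.** The default backend is a standardised weighted ridge
(α = 1), deterministic and desk-scale fast. The network backend is a
dense relu regressor with inverted dropout, adam, mini-batches, a
validation split, patience-based early stopping and best-weight
restore; the full-scale protocol (layers 2000/1000/250, dropout 0.5,
2000 epochs, batch 100, validation 0.2, patience 1000) is preserved in
`ClockSpec`'s defaults, while `ClockSpec.desk_scale()` (layers
64/32/16, 200 epochs, patience 100) is what a laptop-sized run or the
test suite uses. Both backends satisfy the same predict contract. Age
is age at recruitment throughout, because markers are recruitment
measurements.

**Shrinkage and the bias correction.** Any regression of age on noisy
markers shrinks predictions toward the mean age; the training-set
slope of predicted on true age is ≈ R². A latent shift of δ years
(e.g. a planted case effect) therefore surfaces in raw gaps as ≈ R²·δ.
`predict(..., correct_bias=True)` divides centred predictions by that
training slope — the standard age-bias (slope) correction — restoring
the latent scale at the cost of inflating residual variance by ≈ 1/R².
The correction is off by default (matching the uncorrected age-gap
convention, where age at baseline is instead included as a model
covariate); recovery tests and the acceptance script enable it because
their target is the latent-years scale. Recovery tests additionally
use a low-noise generator setting (σ = 3, clock r ≈ 0.95) so that
latent-scale recovery is measured with useful precision; calibration
and heteroskedasticity tests use the default weak-clock setting.

**Gaps.** gap_o = predicted_o − A; the composite gap is the mean of
the six non-hepatic predicted ages minus A, so perturbing the hepatic
clock never moves the composite.

## Genetic scores

score_i = Σ_v dosage_iv × logOR_v. Dosages may be hard genotypes
{0,1,2} or continuous [0,2]; no rounding. Missing dosage cells are
mean-imputed from the variant's sample mean (count reported); panel
variants absent from the genotypes raise in strict mode and are
skipped with a listing otherwise (the convention when a few panel
variants were never imputed in the genotype data). Pathway panels
partition the master panel; the ARMS2 panel is the single
rs10490924-role variant; epigenetic-clock panels are sized 24 (IEAA),
9 (HannumAge) and 12 (PhenoAge). Scaled scores are
(score − ref mean)/ref SD over a declared reference sample — by
default the genetic-association analysis sample (participants with
unknown status, i.e. no GP data, who never entered training or
testing); centering is optional since per-SD slopes are invariant to
it. The shipped variant panels are synthetic stand-ins: the two named
variants keep their field roles and effect magnitudes, but coordinates
and weights are generated, not literature look-ups.

## Association suite

Age-gap models: OLS of one organ's gap on the incident-case indicator
(primary exposure) adjusted for age at baseline, ancestry PCs 1–10,
pack-years, alcohol (categorical with "missing" level) and BMI, fitted
on matched-test controls plus incident cases only — training
participants never enter association fits. Strata are
{all, male, female} × {all, <60, ≥60}; the 60.0-year boundary lands in
the upper stratum. The joint model adds the other six organ gaps and
refuses perfectly collinear gap pairs by name. Genetic models replace
the case indicator with a scaled score (years per SD). The logistic
risk-factor model regresses incident status on age, sex, BMI,
pack-years, both single-variant dosages, the overall scaled score and
the ten PCs; Newton is tried first with an L-BFGS fallback, and
separation or rank deficiency yields flagged, estimate-free rows
rather than exceptions.

Intervals are reported at the 97.5% level — matching the bracket
convention of the results this mirrors, which may itself be a
mislabelled 95% — with conventional 95% intervals always alongside;
all recovery tests use the 95% interval. Significance is two-sided
p < 0.05 with no multiplicity correction; a Benjamini–Hochberg column
is emitted for transparency but never drives verdicts. Every result
row records its exact model formula.

## Numerical choices and degenerate inputs

- One RNG stream per generator stage (CRC32 of the stage label mixed
  into the seed sequence), so regenerating one stage never perturbs
  another and every stage is bitwise reproducible.
- Liability intercept: Brent root-finding on [−40, 15]; a zero target
  yields no cases.
- Zero-variance ages → all clock weights 1. Empty or non-finite panels
  are rejected before training. Clocks require ≥ 30 rows by default.
- Matching with an unreachable tolerance raises an error naming the
  offending variable; `match=False` (or all-infinite tolerances) gives
  a simple random test subset.
- Zero-SD scores cannot be scaled (error); a zero-carrier family is
  removed as underpowered without a fit.
- Constant (all-zero) gaps fit cleanly and are flagged `degenerate`.

## Problem sizes

The test suite runs cohorts of 2–40 k participants: recovery banks use
20 fixed seeds at n = 20,000 (case gap effect, ~600 incident cases) and
n = 40,000 (disease odds ratio, ~1300 cases), type-I error uses 200
simulations at n = 1,500, and the phenotyping filter bank 20 seeds at
n = 12,000. The acceptance script simulates 40,000 participants by
default. These sizes put Monte-Carlo error well below the planted
effects for the recovery checks; individual descriptive quantities at
the paper's effect magnitudes (0.01–0.03 y/SD genetic slopes, ~0.2 y
gap differences) remain noise-dominated at any desk scale — the
package reports them as computed and asserts only the property-based
checks above.

## Known limitations

- The chained-equations engine produces one completed dataset; multiple
  imputation with pooled inference is out of scope.
- The network backend is CPU-bound numpy; the full 2000/1000/250
  protocol is configured but not desk-practical.
- Whether real analyses of this design required significance on *all*
  or *any* risk factors during family validation is ambiguous; the
  configurable retention rule records, rather than resolves, this.
- Time-to-event modelling, Mendelian-randomisation follow-ups,
  genotype-array QC and figure rendering are deliberately out of scope.
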