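# Methods

`turtledose` links the amount of plastic found in a dead sea turtle's
gastro-intestinal tract (GIT) to the probability that the ingested plastic
killed it. The difficulty is that the outcome is only partially observed: a
necropsy classifies each death as **KNP** (known, not plastic — e.g. boat
strike or drowning in fishing gear), **KP** (known, plastic — gut impaction
or perforation), **Ind** (indeterminate — substantial plastic present plus
other plausible causes), or **Ukn** (unknown). KNP animals act as a
statistical control group, assumed to die at random with respect to their
plastic load.

## 1. Debris-count model

Let `y_i` be the number of plastic items recovered from animal `i`. Counts
are heavily over-dispersed (a handful of animals carry tens to hundreds of
items), so we model

    y_i ~ NB(mu_i, k),    log mu_i = x_i' beta,

a negative-binomial (NB2) regression with log link and size parameter `k`
(variance `mu + mu^2 / k`). Candidate models combine cause of death (C),
age class (A) and species (S): codes `0, C, CA, CS, CAS, CA:S`, where
`CA:S` is read as the three main effects plus the cause x age interaction
(the only interaction the model family admits; the shorthand is ambiguous
and this reading is documented here as the package's choice). Coefficients
and `k` are estimated jointly by maximum likelihood (statsmodels, BFGS at
its default gradient tolerance with an L-BFGS fallback);
`AIC = 2(p + 1) − 2 logL`, the `+1` counting the estimated dispersion.
Models are ranked by AIC with a two-unit difference flagged as a
significant improvement and ties broken toward fewer parameters. Adequacy
is checked with a Pearson chi-square statistic against the residual degrees
of freedom.

Factor levels with all-zero counts (hatchlings by default) produce
quasi-complete separation: the fitted coefficient diverges and its standard
error explodes. Fits detect this (|coef| > 20 on the log scale with
SE > 1e3, or a singular Hessian) and flag the terms rather than fail;
reference levels default to cause = Ind (first alphabetical), age = adult,
species = green, all configurable, and fall back to the first observed
level when the configured reference is absent so the design stays full
rank.

The hypothesised ordering Ukn & KNP < Ind < KP is tested with all six
pairwise Wald contrasts on the cause effects, Holm-adjusted (conservative,
assumption-light), and summarised as a compact letter display: levels are
vertices, non-significant pairs are edges, every maximal clique of that
graph gets one letter, so two levels share a letter only if they are not
significantly different after correction.

## 2. Interval-valued mortality labels and the Monte Carlo logistic fit

Each cause category maps to an interval on the probability that death was
due to plastic: KNP → [0,0], KP → [1,1], Ukn and Ind → [0,1]. A
*conservative* variant relabels KP → [0,1], allowing that a plastic
diagnosis may itself be wrong.

The dose-response is a logistic regression of this response on the debris
load. Point-labelled records enter as fixed 0/1; each [0,1] record receives
an independent Uniform(0,1) draw; the model is fitted; and the cycle
repeats (1,000 replicates by default). The ensemble of per-replicate
coefficients is summarised by its medians and its pointwise min/max
envelope.

Fractional responses enter the likelihood in Bernoulli form,

    logL(b) = sum_i [ y_i log p_i + (1 − y_i) log(1 − p_i) ],
    p_i = logistic(x_i' b),

which is linear in `y`: a record with fractional response `y` is exactly
equivalent to a weighted pair (response 1 with weight `y`, response 0 with
weight `1 − y`). This "fractional logit" convention makes the AIC
well-defined (`2p − 2 logL`). The fit is a Newton–Raphson iteration with
step-halving on the exact gradient/Hessian, standard errors from the
observed information; perfect separation is flagged (|coef| > 20) with
capped iterations, never raised; rank-deficient designs are an error.

Three candidate designs:

| code | covariates | load term |
|------|-----------|-----------|
| M1 | count + CCL | count |
| M2 | count + CCL + number-weight residual | count |
| M3 | count/CCL + age class | count/CCL |

The number–weight (NW) residual is the residual from an OLS regression of
total debris mass on item count over records with ≥ 1 item and a recorded
mass — an index of the item-size mix that avoids the collinearity of
including mass directly. Records with counted but unweighed debris are
excluded from M2 fits only (the exclusion count is reported); because M2 is
then fitted to fewer records its AIC is not strictly comparable to M1/M3,
which is why the selection table carries an `n_excluded` column and why
predictions are always driven by M3 (count/CCL + age class), the model
carrying the ecologically relevant covariates, rather than by the
table-best.

Within a replicate the same uniform draws are reused across all model
specs, so AIC comparisons are paired; per-spec AICs are aggregated across
replicates as the mean (median also emitted); the standard ("a") and
conservative ("b") label variants are ranked separately because their
responses come from different data. Replicates failing rank checks are
excluded and counted; more than 5% failures aborts. Draws for replicate
`r` come from `default_rng([seed, r])`, so any replicate is reproducible
from `(seed, r)` and the whole ensemble is bit-reproducible.

**What the estimator targets.** The Monte Carlo fit estimates the
*label-propensity* curve — the probability that a death would be attributed
to plastic at a given load — not a latent physiological hazard. Two
mechanisms separate the two: unresolved records enter as Uniform(0,1) noise
with mean 1/2 regardless of load, shrinking the slope toward zero in
proportion to the unresolved fraction (~65% under the default cohort
composition, where unknown causes dominate); and any competing-risk
attribution of the form p/(p+h) compresses the logit scale by a factor of
roughly (1 − p). Consequently the replicate-slope envelope sits well below
the generator's latent slope under default conditions; what the procedure
does recover — and what the tests assert — is the qualitative positive
dose-response, its significance distribution, and the widening of
uncertainty under the conservative relabelling.

## 3. Dose-response products

For a reference animal (defaults: the cohort's median CCL of 43.5 cm,
juvenile age class) the linear predictor is affine in load, so

* `mortality_at_load` evaluates `logistic(a + b·load)`;
* `invert_for_probability` solves for the load at a target probability in
  closed form, requiring a positive load coefficient; callers wanting whole
  items round up;
* "certain death" is read as numerically-indistinguishable-from-1: the
  first load with `p ≥ 1 − 5e-3` (configurable), since a logistic curve
  never attains 1 exactly;
* `population_ed50` averages the per-animal curves over the observed mix of
  CCL and age classes and finds the 50% crossing by monotone root-finding —
  distinct from, and generally different to, the reference-animal ED50.

Curves are evaluated on an integer load grid (0–250 by default) with the
median-coefficient curve and pointwise min/max envelopes over all replicate
curves; the envelope contains the median by construction and the median
curve is strictly monotone whenever the median load coefficient is
positive.

## 4. Stranding-register presence/absence model

Stranding-register necropsy reports are too coarse for counts, so debris is
scored present/absent and modelled by binary logistic regression on cause
of death, a binary age class (adult vs not) and a binary examination
variable (GIT examined at any level > 0 vs not). Cause uses cell-means
coding — no intercept, one coefficient per observed cause level — so all
four cause log-odds are reported directly; their standard errors refer to
cell log-odds. Species is never included (most species have too few
records). Candidates are the power set of {cause, adult, exam} (8 models)
ranked by AIC; pairwise cause comparisons reuse the Holm/letter-display
machinery. Examination levels score how thoroughly the GIT was inspected
(0 none … 3 sieved); gut plication from ingested line is visible without
opening the GIT, which is why level-0 records can still be debris-positive.

## 5. Synthetic data generator

No raw data are deposited, so the generator emulates the study's recorded
structure; its defaults are fixed study conditions, not tuning knobs:

* **Cohort composition** — 246 animals; age classes hatchling /
  post-hatchling / juvenile / subadult / adult at 22/24/175/13/12; species
  green / hawksbill / loggerhead / flatback / olive ridley / unidentified
  at 160/52/30/1/1/2.
* **Body size** — CCL per age class from a positive-truncated normal
  (means 5.5/12/44/75/95 cm, SDs 0.7/3/13/9/10), chosen so the pooled
  median is ≈ 43.5 cm and the range spans roughly 4–116 cm. Analyses pool
  subadults with adults into a four-level age factor.
* **Debris counts** — NB(mu, k) per age x species cell, k = 0.12 (strongly
  over-dispersed, giving occasional loads in the tens as observed), age
  base means 0/3/2/1/1 items scaled by species factors (greens 1.25,
  hawksbills 0.5, others 0.8). Hatchlings ingest nothing by default (an
  overridable default, not a hard rule).
* **Debris mass** — the sum of per-item lognormal masses
  (log-mean −3.5 log-g, log-SD 1.5; median item ≈ 0.03 g), floored at
  0.01 g when positive; 11/58 of debris-positive animals have the mass
  missing, exercising the M2 exclusion path.
* **Mortality and labels** — latent propensity
  `p = logistic(−1.4 + 4.2 · count/CCL + age offset)`; the intercept and
  slope were solved from two printed points of the fitted curve (≈22%
  mortality at one item and 50% at ≈14 items for a 43.5 cm animal) before
  any testing. All generated animals are dead; the death is attributed to
  plastic with probability `p / (p + h)` against a constant external hazard
  `h = 0.6`. Plastic deaths are labelled KP with probability 0.6 — only
  when the animal actually carries debris, since the KP diagnosis implies
  debris in the gut; zero-load plastic deaths are labelled Ind — and Ind
  otherwise; external deaths are labelled KNP with probability 0.4 and Ukn
  otherwise, making Ukn the modal label as in the study. The labelling
  probabilities are free parameters of the emulation, not estimates.
* **Stranding records** — the same latent machinery, dichotomised at ≥ 1
  item, observed through a detection filter by examination level
  (default detection probabilities 0.05/0.5/0.7/0.95, required
  non-decreasing; level frequencies 185/345/170/6 of 706). KP records are
  always recorded present, so the synthetic KP cell is separated by
  construction — the presence model flags it rather than failing.

What the generator does **not** emulate: spatial structure of strandings,
debris material types, gut-passage dynamics, temporal trends, and any
dependence of item mass on item count. Tests passing on these cohorts
demonstrate the estimation machinery is correct and well-calibrated under
the assumed structure; they do not validate the biological model against
real necropsy data.

## 6. Numerical choices and degenerate inputs

* Newton iterations: relative tolerance 1e-12, cap 100, step-halving to
  keep the likelihood non-decreasing; Hessian ridge 1e-12 for solvability.
* NB fits: BFGS (maxiter 2000) with L-BFGS fallback; a singular Hessian
  after convergence yields infinite SEs plus separation flags.
* All-zero count response: dispersion unidentifiable — returned with
  `converged=False` and a flag, never an exception.
* Masses below 0.01 g are floored at 0.01 g at generation and enforced as
  a record invariant on read.
* KP with zero debris is an invariant violation on read (row-level error
  with line number).
* Empty load grids, non-monotone grids, non-positive CCL and out-of-range
  exam levels are rejected at construction.
* Pipeline runs are deterministic given the configuration: stage seeds are
  `seed`, `seed+1` (stranding set), `seed+2` (Monte Carlo), the manifest
  stores SHA-256 digests of every artifact and no timestamps.

## 7. Problem sizes used by the test suite and acceptance script

The suite exercises the estimators at the study's scales: cohorts of
n = 246 (necropsy) and n = 706 (stranding records), 1,000 Monte Carlo
replicates in the acceptance script, 10,000-animal cohorts for generator
marginal checks, and simulation batteries of 20–100 cohorts for
selection/contrast recovery with 200–1,000 replicates per ensemble. These
sizes are the package's reporting defaults; all are parameters.

## 8. Known limitations

* The Monte Carlo estimator's attenuation (section 2) means its slope is a
  lower bound on any latent dose effect; magnitudes should be interpreted
  on the label-propensity scale.
* Mean-aggregated AIC over replicates is one defensible summary of a
  random-response ensemble, not a likelihood-theoretic quantity; the median
  is emitted alongside.
* The M2 missing-mass exclusion changes its effective sample size; its AIC
  column is comparable only with that caveat.
* The conservative variant's curve envelope is wider *systematically* but
  not surely on every finite sample — occasional single-seed reversals
  arise because a min/max envelope is itself a noisy statistic.
* Synthetic stranding data always separate the KP cell (KP implies debris
  seen); real registers contain KP records with debris "none noted", which
  is why the study's KP coefficient is finite.
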