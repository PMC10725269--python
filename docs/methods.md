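# Methods

## The model

`fibroprog` implements a continuous-time Markov model of liver-fibrosis
progression in nonalcoholic fatty liver disease (NAFLD).  The state space
has seven ordered compartments: histological fibrosis stages F0–F3,
compensated cirrhosis (CC), decompensated cirrhosis (DC), and death.
Transitions occur only between neighbouring compartments — no stage
jumping — with a common backward rate `kback` shared by F1→F0, F2→F1 and
F3→F2, a fixed small CC→F3 rate (that transition is essentially
unobservable in serial-biopsy data), no recovery from DC, and a direct
death transition from every alive compartment.

The transition intensities carry three covariates:

* **Steatosis change (DSTEA)** and **type-2 diabetes (T2D)** multiply the
  four forward rates below cirrhosis:

  `k_xy,i = k_xy · exp(k_DSTEA · DSTEA) · (1 + beta_T2D · T2D)`

  CC→DC and all backward rates are covariate-free.
* **Stage and age** drive the death hazard:

  `k_death,x = kdeath · exp(lambda_death · x) · exp(k_age · (age − 76.9))`

  with stage index `x` = 0…5 for F0…DC and age in years.  The centering
  constant 76.9 years makes `kdeath` the hazard of a 76.9-year-old F0
  patient.  We assign `x = 4` to CC and `x = 5` to DC, continuing the
  compartment ordering; collapsing both cirrhosis compartments to `x = 4`
  is a defensible alternative, but the monotone choice preserves the
  strictly increasing stage–mortality gradient that motivates the
  exponential form.

Age advances continuously with calendar time, in the likelihood and in
every simulation, so the chain is time-inhomogeneous through the death
hazard.

### Default parameter values

The packaged defaults (`fibroprog/data/default_params.yaml`) are the
maximum-likelihood estimates obtained from a Swedish longitudinal
biopsy-cohort of 129 NAFLD patients followed for up to three decades:
k01 = 0.066, k12 = 0.076, k23 = 0.078, k3CC = 0.11, kback = 0.061,
kCCDC = 0.15, kdeath = 0.071 (all 1/year), lambda_death = 0.21,
k_age = 0.12 per year of age, k_DSTEA = 1.8 per steatosis grade,
beta_T2D = 0.36.  `kCC3_fixed` defaults to 1e-6/year (the value is
arbitrary below ~1e-3; it exists so the generator matrix keeps the full
neighbour topology) and is never estimated.

## Interval transition probabilities

Panel data observe the state only at visits, so the likelihood needs
`P(a→b; t, t+dt)` over multi-year intervals during which age grows.  The
interval is split into sub-steps of at most `age_step` years (default
0.5 y) and each sub-step is propagated with a fourth-order two-node Magnus
exponential: with `A1`, `A2` the generator evaluated at the Gauss–Legendre
nodes of the sub-step,

`P_sub = exp( h/2 (A1 + A2) + h² √3/12 [A1, A2] )`,

which is the transpose-convention Magnus form for the row equation
`dP/dt = P Q(t)`.  At the default sub-step, halving `age_step` changes no
transition probability by more than ~1e-8, and the resulting
log-likelihood agrees with a δ = 1e-3 discrete-time brute-force product to
~1e-10 (the test suite asserts 1e-6 and 1e-4 respectively).  The
commutator term has zero row sums, so the matrices are row-stochastic to
machine precision; entries of order h⁴ can undershoot zero and are clipped
at zero.

The batched exponential itself (`fibroprog._expm.expm_batch`) evaluates a
degree-12 Taylor polynomial in Paterson–Stockmeyer form after scaling each
matrix to 1-norm ≤ 1/2, then squares back per matrix.  One likelihood
evaluation of a 2,000-patient cohort needs ~70,000 exponentials of 7×7
matrices; doing these as five batched BLAS products instead of per-matrix
LAPACK calls is what keeps a full fit in minutes.  The routine is verified
against `scipy.linalg.expm` to better than 1e-10 relative error across
magnitudes in the test suite.

## Likelihood

The chain is initialized at the first biopsy: each patient's likelihood
conditions on the first observed state and multiplies interval
contributions.

* **Staged biopsy**: the probability of the observed stage under the
  interval transition matrix applied to the current state distribution.
* **Alive, stage unknown** (patient refused the biopsy but attended the
  blood visit): the unknown alive state is marginalized; the renormalized
  alive-state vector becomes the mixing distribution for the next
  interval rather than being collapsed to a point.
* **Death at an exact registry date**: the event density — the state
  distribution propagated to the death time, contracted with the
  state-specific death intensity at that time.  Survival before the death
  time is already embedded in the interval matrices, whose death column
  absorbs earlier deaths.  Treating death as interval-censored instead
  would discard the registry dates and weaken the stage–mortality
  gradient; exact-time densities are the natural choice when dates are
  known.

A zero-probability sequence returns −inf with a diagnostic naming the
patient and interval.  Hospitalization for decompensation is representable
as a staged DC observation at the event time.

### The steatosis-change covariate

DSTEA is derived from the observed grades, per interval.  The default
convention, `carry_forward`, uses the most recent observed grade change at
or before the interval start (zero until two grades have been seen).  Its
defining property is that the covariate is known at the start of each
interval, which makes the fitted model a coherent generative process: the
rates in force before a death never depend on a biopsy that was never
performed.  That coherence is what lets the synthetic-data generator
simulate from exactly the model the likelihood evaluates, so
simulate-then-refit experiments are unbiased.  The alternative
`interval_change` convention (grade at the interval's end minus the last
grade observed at its start, zero when either endpoint is missing) is
available in the reader for sensitivity analyses; it is not the default
precisely because intervals ending in death or refusal have no end grade.

## Estimation

Rates are optimized as logarithms, the T2D effect as `log(1 + beta_T2D)`
(bounded below at −1), and the remaining coefficients on their natural
scale.  Optimization runs a short Nelder–Mead from the supplied start
(150 evaluations by default) followed by L-BFGS-B with finite-difference
gradients, relative function tolerance 1e-9.  Non-convergence is flagged
on the result, never raised.  Relative standard errors come from the
inverse of a central-difference Hessian on the transformed scale mapped
back by the delta method; if the Hessian is not positive definite the
estimates are returned without standard errors and a reason.

Bootstrap confidence intervals resample patients with replacement, refit
each replicate starting from the full-data estimates, and report
percentile intervals (90% by default, matching the reported analysis,
which used 2,000 replicates); non-convergent replicates are dropped and
counted, with a warning above 5%.

The stepwise covariate machinery tests one added parameter at a time
(`CovariateSpec`: linear `1 + θ(x − median)`, exponential
`exp(θ(x − median))`, or proportional `1 + θ·x` multipliers on the forward
rates or the death hazard) with a likelihood-ratio test on one degree of
freedom: forward inclusion at α = 0.05, backward elimination at the
stricter α = 0.01.  Exhaustive per-transition screening of many covariates
across all functional forms is deliberately out of scope.

## Stochastic simulation

Trajectories are simulated exactly.  Non-death transitions are homogeneous
within a covariate interval; the age-growing death hazard is handled by
thinning: events are proposed with the total rate evaluated at the oldest
age on the remaining horizon and accepted with the ratio of the actual to
the bounding rate.  A vectorized batch version (`simulate_end_states`)
runs the same scheme across whole virtual cohorts.  Agreement between the
simulator and the matrix-exponential transition probabilities — including
the inhomogeneous death fraction — is asserted in the test suite at three
binomial standard errors (plus a 3/n floor, since a pure standard-error
band is degenerate for probabilities near zero or one).

## The synthetic cohort generator

`generate_cohort` emulates the observation design of the Swedish
serial-biopsy study: a baseline biopsy and two follow-ups with inter-visit
intervals Normal(13.8, SD 1.5) and Normal(10.3, SD 3.9) years (truncated
at one year); biopsy refusal at follow-ups 1 and 2 with probabilities
20/129 and 26/103, observed as alive-unstaged visits; deaths recorded at
their exact simulated times, truncating the record.  Histological
steatosis evolves between visits by a ±1-grade random walk with stay
probability 0.6, reflected at grades 0 and 3 — chosen only to give the
DSTEA covariate a non-degenerate spread, not as a claim about real
steatosis dynamics.

Quantities the source cohort does not report in its main text are
configurable defaults chosen as a realistic biopsy-referral NAFLD mix:
baseline stage proportions (0.30, 0.30, 0.20, 0.15, 0.05) over F0–CC,
baseline steatosis proportions (0.05, 0.35, 0.35, 0.25) over grades 0–3,
T2D prevalence 0.30, and baseline age Normal(55, 10) truncated to
[25, 80] years (55 is a clinically meaningful severity cut-point for this
population).  Under these defaults roughly half to three-fifths of a
cohort dies over the ~24-year follow-up, comparable to the 58/129 deaths
of the design being emulated.

What the generator deliberately does not emulate: biomarker trajectories
(ALT/AST, NAS subscores), cause-specific mortality, informative refusal or
visit timing (refusals are independent of disease state), biopsy sampling
error and stage misclassification, and between-patient rate heterogeneity
beyond the modelled covariates.  Passing recovery tests therefore show
that the estimator inverts the model's own data-generating process at the
study's censoring structure — not that the model is correct for any real
cohort.

## Trial simulation

`simulate_trial` builds virtual placebo arms from summary characteristics
(baseline stage proportions or exact counts, T2D proportion, truncated-
normal age, a constant steatosis-change covariate applied over the whole
study) and simulates `n_replicates` independent cohorts.  Each replicate
reports the mean fibrosis stage at end of treatment over surviving
patients, per-compartment proportions, and the fibrosis progression rate
(FPR): per-patient (stage at end − stage at entry)/years, averaged over
patients alive at the end, with F0–F3 scored 0–3 and both cirrhosis
compartments scored 4 (`cap4`) or DC scored 5 (`dc_distinct`).  Both
conventions are exposed because published progression-rate summaries
differ in whether decompensation counts as worsening; deaths are excluded
from stage summaries, mirroring biopsy-at-end-of-trial designs.  Across
replicates the median and 2.5th/97.5th percentiles are reported.
Replicate-to-replicate spread reflects cohort-level sampling (patient
covariates and trajectories), so it shrinks like one over the square root
of the cohort size, a scaling the test suite asserts.

## Numerical and testing choices

* Degenerate inputs: `dt = 0` returns the identity matrix; all-zero rates
  are legal (frozen chain) and exercised by tests; a patient with a single
  observation contributes zero log-likelihood.
* Tie-break in stepwise search: when several forward candidates pass, the
  caller ranks by p-value; `lrt_covariate_step` itself is a single-step
  primitive.
* Test problem sizes: the simulate-then-refit recovery test uses one
  2,000-patient cohort (≈5–7 min on one CPU); the simulation-vs-matrix
  oracle uses 6 random settings × 20,000 trajectories (a per-entry
  3-standard-error band over many more cells would false-alarm by
  construction); the type-I-error study of the covariate search uses 100
  datasets of 500 patients with a deathless single-interval design so each
  of its 200 maximum-likelihood fits takes well under a second, and
  accepts 1–11 rejections of 100 at α = 0.05.
* Reproducibility: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; the CLI records the seed and input-config
  hashes in a `.meta.json` sidecar next to each output.

## Known limitations

* No inter-individual random effects: serial-biopsy panels with two or
  three visits per patient cannot identify them.
* The likelihood treats refusal and visit times as non-informative.
* Forward-rate covariates are constant within an observation interval;
  continuous within-interval steatosis dynamics are not modelled.
* The death hazard aggregates all causes; separating liver-related from
  cardiovascular mortality would need cause-of-death data.
* Short-horizon behaviour (under ~1–2 years) is an extrapolation: the
  generating design's visits are ~10–14 years apart.
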