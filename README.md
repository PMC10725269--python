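# fibroprog

Continuous-time Markov modelling of liver-fibrosis progression in
nonalcoholic fatty liver disease (NAFLD): covariate-modified transition
intensities, interval-censored maximum-likelihood estimation, bootstrap
uncertainty, clinical-trial simulation of placebo arms, and a synthetic
serial-biopsy cohort generator.

Fibrosis stage is the best predictor of end-stage liver disease and
mortality in NAFLD, but it is observed only at sparse, invasive biopsies,
often a decade apart, with deaths and refused biopsies censoring the
picture.  `fibroprog` is for biostatisticians and pharmacometricians who
need to (a) estimate stage-transition rates from such panel data and
(b) predict how a trial cohort's fibrosis will drift under placebo, given
its baseline stage mix, age, diabetes status, and steatosis dynamics.

## The model

Seven ordered compartments — fibrosis stages F0–F3, compensated (CC) and
decompensated (DC) cirrhosis, and death — with transitions only between
neighbours, a shared backward rate k_back for F1–F3, and a death
transition from every alive state.  Covariates modify the intensities:

    k_xy,i    = k_xy · exp(k_DSTEA · ΔSTEA) · (1 + β_T2D · T2D)      x→y below CC→DC
    k_death,x = k_death · exp(λ_death · x) · exp(k_age · (Age − 76.9))   x = 0…5

where ΔSTEA is the change in histological steatosis grade between visits
and age advances continuously, making the chain time-inhomogeneous.
Interval transition probabilities are matrix exponentials of the
generator, composed over sub-steps as age grows; the likelihood of a
patient's record conditions on the first biopsy, marginalizes
"alive, stage unknown" visits, and uses exact-time event densities for
registry deaths.  See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic 129-patient serial-biopsy cohort at the packaged
reference estimates, refit the seven transition rates, and simulate a
40-patient placebo arm:

```python
from fibroprog import (CohortDesign, ModelParameters, TrialSpec,
                       generate_cohort, fit_mle, simulate_trial)

params = ModelParameters()          # packaged cohort estimates
records, _ = generate_cohort(CohortDesign(), params, seed=7)
print(f"cohort: {len(records)} patients, "
      f"{sum(r.died for r in records)} deaths over follow-up")

fit = fit_mle(records, init=params,
              fixed={"lambda_death", "k_age", "k_DSTEA", "beta_T2D"})
for name in ("k01", "k12", "k23", "k3CC", "kback", "kCCDC", "kdeath"):
    print(f"  {name:7s} {getattr(fit.estimates, name):.3f} /year "
          f"(RSE {fit.rse[name]:.2f})")

spec = TrialSpec(n_patients=40, study_length=2.0,
                 baseline_stage=(8, 8, 8, 8, 8), stage_counts=True,
                 age_mean=50.0, age_sd=0.0, n_replicates=1000, seed=1)
s = simulate_trial(spec, params).summary
print(f"EOT mean stage: median {s.loc['median','mean_stage_eot']:.2f} "
      f"(95% PI {s.loc['q2.5','mean_stage_eot']:.2f}-"
      f"{s.loc['q97.5','mean_stage_eot']:.2f})")
```

Output:

```
cohort: 129 patients, 81 deaths over follow-up
  k01     0.042 /year (RSE 0.31)
  k12     0.177 /year (RSE 0.36)
  k23     0.060 /year (RSE 0.29)
  k3CC    0.087 /year (RSE 0.27)
  kback   0.081 /year (RSE 0.25)
  kCCDC   0.189 /year (RSE 0.32)
  kdeath  0.067 /year (RSE 0.11)
EOT mean stage: median 2.05 (95% PI 1.92-2.21)
```

At 129 patients with decade-long gaps between biopsies the individual
rates carry ~30% relative standard errors — the motivation for the
recovery experiments below, which show the estimator is unbiased and
tightens as cohorts grow.  The trial summary says a 40-patient arm with
eight patients per baseline stage (mean stage 2.0) drifts to a median
mean stage of 2.05 after two years, with cohort-level sampling spanning
1.92–2.21.

The same pipeline is available from the shell:

```sh
fibroprog generate --seed 11 --out cohort.csv
fibroprog fit --data cohort.csv --out fit.json
fibroprog simulate --spec trial.yaml --seed 5 --out trial
fibroprog fpr --spec trial.yaml --horizons 1,2,5 --out fpr.csv
fibroprog bootstrap --data cohort.csv --n 2000 --level 90 --seed 3 --out ci.csv
```

Each command writes a `.meta.json` sidecar (seed, input hashes, versions)
so any output is reproducible from its metadata.

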