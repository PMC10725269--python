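"""Maximum-likelihood fitting, bootstrap, and the likelihood-ratio search."""

import numpy as np
import pytest

from fibroprog import (
    CohortDesign,
    CovariateSpec,
    ModelParameters,
    Observation,
    ObsKind,
    PatientRecord,
    bootstrap_ci,
    fit_mle,
    generate_cohort,
    lrt_covariate_step,
    transition_matrix,
)
from fibroprog.model import CovariateProfile
from fibroprog.params import ESTIMATED_FIELDS

S = ObsKind.STAGE

ALL_FIXED = set(ESTIMATED_FIELDS)


def single_interval_cohort(params, n, dt, rng, stage_probs=(0.3, 0.3, 0.2, 0.15, 0.05)):
    """Two-visit records sampled exactly from the interval transition law.

    Uses a deathless parameter set so the end state is a plain draw from
    the transition-matrix row (no event-time bookkeeping needed).
    """
    assert params.kdeath == 0.0
    p_mat = transition_matrix(params, CovariateProfile(), 50.0, dt)
    records = []
    for i in range(n):
        s0 = int(rng.choice(5, p=np.asarray(stage_probs)))
        s1 = int(rng.choice(7, p=p_mat[s0]))
        records.append(
            PatientRecord(
                f"Q{i:04d}",
                (Observation(0.0, S, state=s0), Observation(dt, S, state=s1)),
                t2d=False,
                age_at_first_biopsy=50.0,
            )
        )
    return records


@pytest.fixture(scope="module")
def deathless_params():
    return ModelParameters(kdeath=0.0, k_age=0.0, lambda_death=0.0)


class TestFitMle:
    def test_null_t2d_effect_recovered_within_two_se(self):
        """Data generated without a diabetes effect yield an estimate
        compatible with zero."""
        truth = ModelParameters(beta_T2D=0.0)
        records, _ = generate_cohort(
            CohortDesign(n_patients=300), truth, seed=42
        )
        fit = fit_mle(
            records,
            init=truth.replace(beta_T2D=0.05),
            fixed=ALL_FIXED - {"beta_T2D"},
            simplex_maxfev=0,
        )
        assert fit.converged
        assert fit.rse is not None
        se = abs(fit.estimates.beta_T2D) * fit.rse["beta_T2D"]
        # RSE is SE/estimate, so SE = |estimate| * RSE even near zero
        assert abs(fit.estimates.beta_T2D) <= 2.0 * max(se, 0.05)

    def test_multistart_stability(self, ref_params, small_cohort):
        """Jittered starting points (+-50%) converge to the same optimum."""
        records = small_cohort[0]
        free = {"k01", "k12", "kback", "kdeath"}
        rng = np.random.default_rng(11)
        lls = []
        for _ in range(5):
            start = ref_params.replace(
                **{k: getattr(ref_params, k) * rng.uniform(0.5, 1.5) for k in free}
            )
            fit = fit_mle(
                records,
                init=start,
                fixed=ALL_FIXED - free,
                compute_se=False,
                simplex_maxfev=60,
            )
            assert fit.converged
            lls.append(fit.log_likelihood)
        assert max(lls) - min(lls) < 0.1

    def test_reports_rse_from_hessian(self, deathless_params, rng):
        records = single_interval_cohort(deathless_params, 400, 10.0, rng)
        fit = fit_mle(
            records,
            init=deathless_params,
            fixed=ALL_FIXED - {"k01", "k12", "kback"},
            simplex_maxfev=0,
        )
        assert fit.converged
        assert set(fit.rse) == {"k01", "k12", "kback"}
        assert all(0 < v < 1.0 for v in fit.rse.values())


class TestBootstrap:
    def test_single_replicate_gives_degenerate_interval(self, deathless_params, rng):
        records = single_interval_cohort(deathless_params, 120, 10.0, rng)
        table = bootstrap_ci(
            records,
            n_boot=1,
            seed=5,
            init=deathless_params,
            fixed=ALL_FIXED - {"k01"},
            simplex_maxfev=0,
        )
        row = table.set_index("parameter").loc["k01"]
        assert row["ci_lo"] == row["ci_hi"] == row["boot_mean"]

    def test_homogeneous_population_concentrates(self, deathless_params, rng):
        """Resampling a cohort made of one duplicated patient always returns
        the same dataset, so every replicate reproduces the full-data
        estimate."""
        base = single_interval_cohort(deathless_params, 1, 10.0, rng)[0]
        records = [
            PatientRecord(f"C{i}", base.observations, base.t2d, base.age_at_first_biopsy)
            for i in range(100)
        ]
        table = bootstrap_ci(
            records,
            n_boot=4,
            seed=9,
            init=deathless_params,
            fixed=ALL_FIXED - {"k01"},
            simplex_maxfev=0,
        )
        row = table.set_index("parameter").loc["k01"]
        assert row["ci_hi"] - row["ci_lo"] <= 1e-6 * max(row["estimate"], 1e-9)

    def test_invalid_arguments(self, deathless_params, rng):
        records = single_interval_cohort(deathless_params, 10, 10.0, rng)
        with pytest.raises(ValueError):
            bootstrap_ci(records, n_boot=0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(records, n_boot=1, level=120.0, seed=1)


class TestLrtStep:
    def test_uninformative_candidate_gives_p_one(self, deathless_params, rng):
        """A covariate whose multiplier is identically one cannot improve
        the likelihood: p = 1, not included."""
        records = single_interval_cohort(deathless_params, 150, 10.0, rng)
        candidate = CovariateSpec(
            name="null", values=lambda rec: 0.0, form="exponential", target="forward"
        )
        step = lrt_covariate_step(
            records,
            candidate,
            init=deathless_params,
            fixed=ALL_FIXED - {"k01", "k12"},
            simplex_maxfev=0,
        )
        assert step.p_value == pytest.approx(1.0, abs=1e-6)
        assert not step.include

    def test_true_steatosis_effect_detected(self, ref_params):
        """With the steatosis effect active in the data (k_DSTEA = 1.8) and
        absent from the base model, the forward step detects it
        decisively."""
        records, _ = generate_cohort(CohortDesign(n_patients=200), ref_params, seed=77)
        base_init = ref_params.replace(k_DSTEA=0.0)
        candidate = CovariateSpec(
            name="dstea", values="dstea", form="exponential", target="forward"
        )
        step = lrt_covariate_step(
            records,
            candidate,
            init=base_init,
            fixed=ALL_FIXED - {"k01", "k12", "k23"},
            simplex_maxfev=0,
        )
        assert step.include
        assert step.p_value < 1e-4
        assert step.theta == pytest.approx(1.8, abs=0.9)

    def test_direction_validation(self, deathless_params, rng):
        records = single_interval_cohort(deathless_params, 10, 10.0, rng)
        candidate = CovariateSpec(name="x", values=lambda rec: 0.0)
        with pytest.raises(ValueError, match="direction"):
            lrt_covariate_step(records, candidate, direction="sideways")


class TestTimeUnitEquivarianceOfMle:
    def test_rates_scale_with_the_time_unit(self, deathless_params, rng):
        """Fitting the same data expressed in months recovers rates exactly
        twelve times smaller."""
        records = single_interval_cohort(deathless_params, 150, 10.0, rng)
        months = [
            PatientRecord(
                r.id,
                tuple(
                    Observation(o.time * 12.0, o.kind, o.state, o.steatosis)
                    for o in r.observations
                ),
                r.t2d,
                r.age_at_first_biopsy * 12.0,
            )
            for r in records
        ]
        fixed = ALL_FIXED - {"k01", "kback"}
        fit_y = fit_mle(records, init=deathless_params, fixed=fixed,
                        compute_se=False, simplex_maxfev=0)
        p_m = deathless_params.replace(
            **{k: getattr(deathless_params, k) / 12.0
               for k in ("k01", "k12", "k23", "k3CC", "kback", "kCCDC",
                         "kCC3_fixed")},
            age_center=deathless_params.age_center * 12.0,
        )
        fit_m = fit_mle(months, init=p_m, fixed=fixed, compute_se=False,
                        simplex_maxfev=0, age_step=6.0)
        assert fit_m.estimates.k01 == pytest.approx(fit_y.estimates.k01 / 12.0, rel=5e-3)
        assert fit_m.estimates.kback == pytest.approx(
            fit_y.estimates.kback / 12.0, rel=5e-3
        )
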