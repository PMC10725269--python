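"""Trajectory sampling, cohort construction, and trial summaries."""

import numpy as np
import pytest

from fibroprog import (
    CovariateProfile,
    DiseaseState,
    ModelParameters,
    Trajectory,
    TrialSpec,
    compute_fpr,
    sample_cohort,
    simulate_end_states,
    simulate_trajectory,
    simulate_trial,
    transition_matrix,
)

ZERO = ModelParameters(
    k01=0, k12=0, k23=0, k3CC=0, kback=0, kCCDC=0, kdeath=0,
    lambda_death=0, k_age=0, k_DSTEA=0, beta_T2D=0, kCC3_fixed=0,
)


def traj(points, t_end):
    times, states = zip(*points)
    return Trajectory(np.asarray(times, float), np.asarray(states, int), t_end)


class TestSimulateTrajectory:
    def test_frozen_chain_stays_put(self, rng):
        t = simulate_trajectory(ZERO, CovariateProfile(), 2, 50.0, rng)
        assert t.times.tolist() == [0.0] and t.states.tolist() == [2]

    def test_cannot_start_dead(self, ref_params, rng):
        with pytest.raises(ValueError):
            simulate_trajectory(ref_params, CovariateProfile(), 6, 1.0, rng)

    def test_neighbour_moves_only(self, ref_params, rng):
        for _ in range(60):
            t = simulate_trajectory(
                ref_params,
                CovariateProfile(dstea=1, t2d=True, age_at_start=70.0),
                0,
                15.0,
                rng,
            )
            assert np.all(np.diff(t.times) > 0)
            for a, b in zip(t.states[:-1], t.states[1:]):
                assert b == DiseaseState.DEATH or abs(b - a) == 1

    def test_marginal_matches_transition_matrix(self, ref_params, rng):
        """Single-trajectory sampler: state distribution at the horizon vs
        the matrix-exponential row (homogeneous case)."""
        params = ref_params.replace(k_age=0.0)
        cov = CovariateProfile(t2d=True, age_at_start=65.0)
        n = 4000
        counts = np.zeros(7)
        for _ in range(n):
            t = simulate_trajectory(params, cov, 1, 6.0, rng)
            counts[t.final_state] += 1
        p_row = transition_matrix(params, cov, 65.0, 6.0)[1]
        band = 3.0 * np.sqrt(p_row * (1 - p_row) / n) + 3.0 / n
        assert np.all(np.abs(counts / n - p_row) <= band)


class TestBatchedEndStates:
    def test_inhomogeneous_death_fraction(self, ref_params, rng):
        """Thinning under the age-growing hazard: death fraction of
        80-year-old F3 patients over ten years matches the
        time-inhomogeneous transition-matrix death entry."""
        n = 20000
        end, death_t = simulate_end_states(
            ref_params,
            np.zeros(n),
            np.zeros(n),
            np.full(n, 80.0),
            np.full(n, 3),
            10.0,
            rng,
        )
        p_death = transition_matrix(
            ref_params, CovariateProfile(age_at_start=80.0), 80.0, 10.0
        )[3, 6]
        frac = np.mean(end == 6)
        band = 3.0 * np.sqrt(p_death * (1 - p_death) / n) + 3.0 / n
        assert abs(frac - p_death) <= band
        assert np.all(np.isnan(death_t[end != 6]))
        assert np.all(death_t[end == 6] <= 10.0)


class TestSampleCohort:
    def test_exact_counts_give_exact_baseline_mean(self, rng):
        spec = TrialSpec(
            n_patients=40,
            study_length=1.0,
            baseline_stage=(8, 8, 8, 8, 8),
            stage_counts=True,
        )
        cohort = sample_cohort(spec, rng)
        assert len(cohort) == 40
        assert cohort["start_state"].mean() == 2.0

    def test_degenerate_proportions(self, rng):
        spec = TrialSpec(
            n_patients=40, study_length=2.0, baseline_stage=(1, 0, 0, 0, 0),
            t2d_proportion=0.0,
        )
        cohort = sample_cohort(spec, rng)
        assert (cohort["start_state"] == 0).all()
        assert (cohort["t2d"] == 0).all()

    def test_age_truncated_at_18(self, rng):
        spec = TrialSpec(
            n_patients=300, study_length=1.0, baseline_stage=(1, 0, 0, 0, 0),
            age_mean=22.0, age_sd=10.0,
        )
        assert sample_cohort(spec, rng)["age"].min() >= 18.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec(n_patients=10, study_length=1.0, baseline_stage=(0.5, 0.5, 0.5, 0, 0))
        with pytest.raises(ValueError):
            TrialSpec(n_patients=0, study_length=1.0, baseline_stage=(1, 0, 0, 0, 0))


class TestComputeFpr:
    def test_two_stage_progression_arithmetic(self):
        t = traj([(0.0, 0), (4.0, 1), (9.0, 2)], t_end=10.0)
        assert compute_fpr([t]) == pytest.approx(0.2)

    def test_cirrhosis_capping_conventions(self):
        t = traj([(0.0, 4), (5.0, 5)], t_end=10.0)
        assert compute_fpr([t], "cap4") == 0.0
        assert compute_fpr([t], "dc_distinct") == pytest.approx(0.1)

    def test_deaths_excluded_and_all_dead_rejected(self):
        dead = traj([(0.0, 3), (2.0, 6)], t_end=10.0)
        alive = traj([(0.0, 0), (5.0, 1)], t_end=10.0)
        assert compute_fpr([dead, alive]) == pytest.approx(0.1)
        with pytest.raises(ValueError, match="alive"):
            compute_fpr([dead])


class TestSimulateTrial:
    def test_frozen_chain_reproduces_baseline_exactly(self):
        spec = TrialSpec(
            n_patients=40,
            study_length=3.0,
            baseline_stage=(8, 8, 8, 8, 8),
            stage_counts=True,
            n_replicates=20,
            seed=1,
        )
        result = simulate_trial(spec, ZERO)
        assert (result.replicates["mean_stage_eot"] == 2.0).all()
        assert (result.replicates["fpr"] == 0.0).all()

    def test_vanishing_study_length_returns_baseline(self, ref_params):
        spec = TrialSpec(
            n_patients=30,
            study_length=1e-7,
            baseline_stage=(6, 6, 6, 6, 6),
            stage_counts=True,
            n_replicates=10,
            seed=2,
        )
        result = simulate_trial(spec, ref_params)
        assert result.summary.loc["median", "mean_stage_eot"] == pytest.approx(2.0)

    def test_mean_stage_monotone_without_regression_or_death(self, ref_params):
        """With backward rates and death switched off, fibrosis only
        accumulates: mean EOT stage is non-decreasing in study length and
        bounded by the cap-4 score."""
        params = ref_params.replace(
            kback=0.0, kCC3_fixed=0.0, kdeath=0.0, k_age=0.0, lambda_death=0.0
        )
        means = []
        for length in (1.0, 3.0, 8.0):
            spec = TrialSpec(
                n_patients=2000,
                study_length=length,
                baseline_stage=(0.4, 0.3, 0.2, 0.1, 0.0),
                n_replicates=4,
                seed=31,
            )
            m = simulate_trial(spec, params).summary.loc["median", "mean_stage_eot"]
            assert 0.0 <= m <= 4.0
            means.append(m)
        assert means == sorted(means)

    def test_interval_width_shrinks_with_cohort_size(self, ref_params):
        """Quadrupling the cohort halves the across-replicate spread of the
        EOT mean (CLT scaling of the replicate means)."""
        widths = {}
        for n in (25, 100):
            spec = TrialSpec(
                n_patients=n,
                study_length=2.0,
                baseline_stage=(0.2, 0.2, 0.2, 0.2, 0.2),
                age_mean=55.0,
                age_sd=8.0,
                n_replicates=600,
                seed=3,
            )
            summary = simulate_trial(spec, ref_params).summary
            widths[n] = (
                summary.loc["q97.5", "mean_stage_eot"]
                - summary.loc["q2.5", "mean_stage_eot"]
            )
        ratio = widths[100] / widths[25]
        assert 0.4 <= ratio <= 0.625  # 0.5 +- 20%
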