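"""Interval-censored panel-data likelihood of the fibrosis Markov model.

Each patient's likelihood conditions on the first observed state (the chain
is initialized at the first biopsy) and is a product over successive
observation intervals:

* ``STAGE`` endpoint: the transition probability from the current state
  distribution to the observed stage over the interval;
* ``ALIVE_UNSTAGED`` endpoint (refused biopsy, known alive): the unknown
  alive state is marginalized -- the probability of being alive at the
  visit -- and the renormalized alive-state distribution carries forward as
  the mixing distribution of the next interval;
* ``DEATH`` endpoint at an exact registry date: the event density -- the
  state distribution propagated to the death time multiplied by the
  state-specific death intensity at that time (survival up to the death
  time is embedded in the interval transition matrices, whose death column
  absorbs earlier deaths).

A zero-probability observation sequence yields ``-inf`` with a diagnostic
naming the offending patient and interval.

All interval transition matrices of a dataset are computed in one batched
matrix-exponential call per likelihood evaluation, so repeated evaluation
inside an optimizer stays cheap; the observation recursion is vectorized
over patients by interval position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import (
    DEFAULT_AGE_STEP,
    GAUSS_NODE,
    _substep_grid,
    death_rates,
    magnus_propagators,
)
from .params import ModelParameters
from .records import Interval, ObsKind, PatientRecord, derive_intervals

logger = logging.getLogger(__name__)

_KIND_STAGE, _KIND_ALIVE, _KIND_DEATH = 0, 1, 2

COVARIATE_FORMS = ("linear", "exponential", "proportional")

#: transition groups a searched covariate may act on
COVARIATE_TARGETS = ("forward", "death")


@dataclass(frozen=True)
class CovariateSpec:
    """A candidate covariate effect for the stepwise likelihood-ratio search.

    ``values`` names a built-in per-interval quantity (``dstea``, ``t2d``,
    ``age_start``, ``dt``) or is a callable mapping a :class:`PatientRecord`
    to a scalar or per-interval array.  ``form`` is the functional form of
    the rate multiplier in the search, with ``theta`` the single added
    parameter and ``center`` the covariate's centering value (typically the
    median):

    * ``linear``: ``1 + theta * (x - center)``
    * ``exponential``: ``exp(theta * (x - center))``
    * ``proportional``: ``1 + theta * x`` (for 0/1 covariates)

    ``target`` selects the transition group the multiplier applies to:
    all four forward rates, or the death hazard.
    """

    name: str
    values: str | Callable[[PatientRecord], object]
    form: str = "linear"
    target: str = "forward"
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in COVARIATE_FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.target not in COVARIATE_TARGETS:
            raise ValueError(f"unknown covariate target {self.target!r}")
        if not np.isfinite(self.center):
            raise ValueError("covariate centering value must be finite")

    def interval_values(self, record: PatientRecord, intervals: Sequence[Interval]) -> np.ndarray:
        n = len(intervals)
        if callable(self.values):
            vals = np.asarray(self.values(record), dtype=float)
            return np.broadcast_to(vals, (n,)).astype(float)
        if self.values == "dstea":
            return np.array([iv.dstea for iv in intervals], dtype=float)
        if self.values == "t2d":
            return np.full(n, float(record.t2d))
        if self.values == "age_start":
            return np.array([iv.age_start for iv in intervals], dtype=float)
        if self.values == "dt":
            return np.array([iv.dt for iv in intervals], dtype=float)
        raise ValueError(f"unknown covariate source {self.values!r}")

    def multiplier(self, theta: float, values: np.ndarray) -> np.ndarray:
        x = values - self.center if self.form != "proportional" else values
        if self.form == "exponential":
            return np.exp(theta * x)
        return 1.0 + theta * x


class LikelihoodPlan:
    """Preprocessed dataset structure for repeated likelihood evaluation.

    The plan flattens every observation interval of every patient into
    arrays of age sub-steps (length at most ``age_step`` years, each
    propagated by a fourth-order Magnus exponential) and groups intervals
    by their position in the patient's record so the forward recursion
    runs vectorized.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord],
        age_step: float = DEFAULT_AGE_STEP,
        dstea_convention: str = "carry_forward",
        extension: CovariateSpec | None = None,
    ) -> None:
        if not records:
            raise ValueError("empty dataset")
        if not age_step > 0:
            raise ValueError("age_step must be positive")
        self.records = list(records)
        self.age_step = float(age_step)
        self.dstea_convention = dstea_convention
        self.extension = extension
        self.n_patients = len(self.records)

        first_states = []
        iv_dt, iv_dstea, iv_t2d, iv_age0, iv_ext = [], [], [], [], []
        iv_patient, iv_position, iv_kind, iv_end_state, iv_end_age = [], [], [], [], []
        for p, rec in enumerate(self.records):
            first_states.append(int(rec.observations[0].state))
            intervals = derive_intervals(rec, dstea_convention)
            ext_vals = (
                extension.interval_values(rec, intervals)
                if extension is not None
                else np.zeros(len(intervals))
            )
            for j, iv in enumerate(intervals):
                iv_dt.append(iv.dt)
                iv_dstea.append(iv.dstea)
                iv_t2d.append(float(iv.t2d))
                iv_age0.append(iv.age_start)
                iv_ext.append(float(ext_vals[j]))
                iv_patient.append(p)
                iv_position.append(j)
                if iv.end_kind is ObsKind.STAGE:
                    iv_kind.append(_KIND_STAGE)
                    iv_end_state.append(iv.end_state)
                elif iv.end_kind is ObsKind.ALIVE_UNSTAGED:
                    iv_kind.append(_KIND_ALIVE)
                    iv_end_state.append(-1)
                else:
                    iv_kind.append(_KIND_DEATH)
                    iv_end_state.append(-1)
                iv_end_age.append(rec.age_at_first_biopsy + iv.t_end)

        self.first_states = np.asarray(first_states, dtype=int)
        self.iv_dt = np.asarray(iv_dt)
        self.iv_dstea = np.asarray(iv_dstea)
        self.iv_t2d = np.asarray(iv_t2d)
        self.iv_ext = np.asarray(iv_ext)
        self.iv_patient = np.asarray(iv_patient, dtype=int)
        self.iv_kind = np.asarray(iv_kind, dtype=int)
        self.iv_end_state = np.asarray(iv_end_state, dtype=int)
        self.iv_end_age = np.asarray(iv_end_age)
        self.n_intervals = len(iv_dt)
        if self.n_intervals == 0:
            raise ValueError("no observation intervals in dataset")

        # sub-step grid: contiguous per interval, chronological within it
        n_sub, sub_h, sub_age = [], [], []
        for dt, age0 in zip(iv_dt, iv_age0):
            m, h, mids = _substep_grid(dt, self.age_step)
            n_sub.append(m)
            sub_h.append(np.full(m, h))
            sub_age.append(age0 + mids)
        self.iv_n_sub = np.asarray(n_sub, dtype=int)
        self.iv_sub_start = np.concatenate(([0], np.cumsum(self.iv_n_sub)[:-1]))
        self.sub_h = np.concatenate(sub_h)
        self.sub_age = np.concatenate(sub_age)
        rep = np.repeat(np.arange(self.n_intervals), self.iv_n_sub)
        self.sub_dstea = self.iv_dstea[rep]
        self.sub_t2d = self.iv_t2d[rep]
        self.sub_ext = self.iv_ext[rep]
        self.max_n_sub = int(self.iv_n_sub.max())

        # intervals grouped by position within the record
        position = np.asarray(iv_position, dtype=int)
        self.positions = [
            np.flatnonzero(position == j) for j in range(int(position.max()) + 1)
        ]

    # -- evaluation -------------------------------------------------------

    def _interval_matrices(
        self, params: ModelParameters, theta_ext: float | None
    ) -> np.ndarray | None:
        fwd_extra = death_extra = None
        if self.extension is not None:
            mult = self.extension.multiplier(float(theta_ext), self.sub_ext)
            if np.any(mult <= 0) or not np.all(np.isfinite(mult)):
                return None  # invalid rate multiplier (e.g. linear form gone negative)
            if self.extension.target == "forward":
                fwd_extra = mult
            else:
                death_extra = mult
        delta = GAUSS_NODE * self.sub_h
        p_sub = magnus_propagators(
            params,
            self.sub_dstea,
            self.sub_t2d,
            self.sub_age - delta,
            self.sub_age + delta,
            self.sub_h,
            forward_extra=fwd_extra,
            death_extra=death_extra,
        )
        p_iv = np.broadcast_to(np.eye(7), (self.n_intervals, 7, 7)).copy()
        for k in range(self.max_n_sub):
            sel = self.iv_n_sub > k
            p_iv[sel] = p_iv[sel] @ p_sub[self.iv_sub_start[sel] + k]
        return p_iv

    def _death_intensities(
        self, params: ModelParameters, idx: np.ndarray, theta_ext: float | None
    ) -> np.ndarray:
        dr = death_rates(params, self.iv_end_age[idx])
        if self.extension is not None and self.extension.target == "death":
            mult = self.extension.multiplier(float(theta_ext), self.iv_ext[idx])
            dr = dr * mult[:, None]
        return dr

    def per_patient(
        self, params: ModelParameters, theta_ext: float | None = None
    ) -> np.ndarray:
        """Log-likelihood contribution of each patient (``-inf`` where impossible)."""
        if self.extension is not None and theta_ext is None:
            theta_ext = 0.0
        p_iv = self._interval_matrices(params, theta_ext)
        if p_iv is None:
            return np.full(self.n_patients, -np.inf)

        ll = np.zeros(self.n_patients)
        f = np.zeros((self.n_patients, 7))
        f[np.arange(self.n_patients), self.first_states] = 1.0

        for j, idx in enumerate(self.positions):
            pats = self.iv_patient[idx]
            v = np.einsum("ps,psq->pq", f[pats], p_iv[idx])
            np.clip(v, 0.0, None, out=v)
            contrib = np.empty(len(idx))
            fnew = np.zeros_like(v)

            kinds = self.iv_kind[idx]
            m = kinds == _KIND_STAGE
            if m.any():
                rows = np.flatnonzero(m)
                states = self.iv_end_state[idx[rows]]
                contrib[rows] = v[rows, states]
                fnew[rows, states] = 1.0
            m = kinds == _KIND_ALIVE
            if m.any():
                rows = np.flatnonzero(m)
                alive = v[rows, :6]
                tot = alive.sum(axis=1)
                contrib[rows] = tot
                with np.errstate(invalid="ignore", divide="ignore"):
                    fnew[rows, :6] = alive / tot[:, None]
            m = kinds == _KIND_DEATH
            if m.any():
                rows = np.flatnonzero(m)
                dr = self._death_intensities(params, idx[rows], theta_ext)
                contrib[rows] = (v[rows, :6] * dr).sum(axis=1)
                # terminal observation; the carried state is irrelevant

            bad = ~(contrib > 0)
            if bad.any():
                b = int(np.flatnonzero(bad)[0])
                logger.debug(
                    "zero-probability observation: patient %s, interval %d",
                    self.records[int(pats[b])].id,
                    j,
                )
                ll[pats[bad]] = -np.inf
            ok = ~bad
            with np.errstate(divide="ignore"):
                ll[pats[ok]] += np.log(contrib[ok])
            f[pats[ok]] = fnew[ok]
        return ll

    def loglik(self, params: ModelParameters, theta_ext: float | None = None) -> float:
        return float(self.per_patient(params, theta_ext).sum())


def patient_log_likelihood(
    record: PatientRecord,
    params: ModelParameters,
    age_step: float = DEFAULT_AGE_STEP,
    dstea_convention: str = "carry_forward",
) -> float:
    """Log-likelihood of one patient's observation sequence."""
    if record.n_intervals == 0:
        return 0.0  # a single (conditioning) observation carries no information
    plan = LikelihoodPlan([record], age_step=age_step, dstea_convention=dstea_convention)
    return float(plan.per_patient(params)[0])


def dataset_log_likelihood(
    records: Sequence[PatientRecord],
    params: ModelParameters,
    age_step: float = DEFAULT_AGE_STEP,
    dstea_convention: str = "carry_forward",
) -> float:
    """Sum of independent patient log-likelihood contributions."""
    if not records:
        raise ValueError("empty dataset")
    if all(r.n_intervals == 0 for r in records):
        return 0.0
    plan = LikelihoodPlan(
        [r for r in records if r.n_intervals > 0],
        age_step=age_step,
        dstea_convention=dstea_convention,
    )
    return plan.loglik(params)
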