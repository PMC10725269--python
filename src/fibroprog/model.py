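"""Transition intensities and interval transition probabilities.

The model is a continuous-time Markov chain on seven compartments
(F0, F1, F2, F3, CC, DC, DEATH).  Transitions occur only between
neighbouring fibrosis compartments (no stage jumping); every alive
compartment has a direct transition to death.

Covariate structure:

* the four forward rates below cirrhosis (F0->F1 .. F3->CC) are multiplied
  by ``exp(k_DSTEA * DSTEA) * (1 + beta_T2D * T2D)``, where DSTEA is the
  change in histological steatosis grade between visits and T2D the
  diabetes indicator;
* the death hazard from stage ``x`` at age ``a`` is
  ``kdeath * exp(lambda_death * x) * exp(k_age * (a - age_center))``;
* backward rates and CC->DC carry no covariates.

Because age advances with time, the chain is time-inhomogeneous through the
death hazard.  Interval transition probabilities are computed by splitting
the interval into sub-steps of at most ``age_step`` years, propagating each
sub-step with a fourth-order Magnus exponential (generator evaluated at two
Gauss nodes within the sub-step), and composing the sub-step matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._expm import expm_batch
from .params import ModelParameters
from .states import N_STATES

#: default sub-step length (years) of the piecewise-constant age approximation
DEFAULT_AGE_STEP = 0.5

#: forward transitions below CC->DC: label -> (rate field, from-state, to-state)
FORWARD_TRANSITIONS = {
    "01": ("k01", 0, 1),
    "12": ("k12", 1, 2),
    "23": ("k23", 2, 3),
    "3CC": ("k3CC", 3, 4),
}


@dataclass(frozen=True)
class CovariateProfile:
    """Covariate values applying to one observation interval.

    ``dstea`` is the steatosis-grade change attributed to the interval
    (grades run 0-3, so changes beyond +-3 are impossible; values up to +-4
    are accepted defensively with a warning).  ``age_at_start`` and
    ``interval_length`` are optional annotations used by callers that carry
    the interval context around.
    """

    dstea: float = 0.0
    t2d: bool = False
    age_at_start: float | None = None
    interval_length: float | None = None

    def __post_init__(self) -> None:
        if abs(self.dstea) > 4:
            raise ValueError(f"dstea change {self.dstea} outside the steatosis scale")
        if abs(self.dstea) > 3:
            warnings.warn(
                f"dstea change {self.dstea} exceeds the 0-3 grade range",
                stacklevel=2,
            )
        if self.interval_length is not None and not self.interval_length > 0:
            raise ValueError("interval_length must be positive")


def forward_multiplier(
    params: ModelParameters, dstea: np.ndarray | float, t2d: np.ndarray | float
) -> np.ndarray | float:
    """Covariate multiplier applied to the four forward rates (array-friendly)."""
    return np.exp(params.k_DSTEA * np.asarray(dstea, dtype=float)) * (
        1.0 + params.beta_T2D * np.asarray(t2d, dtype=float)
    )


def forward_rate(params: ModelParameters, transition: str, cov: CovariateProfile) -> float:
    """Covariate-modified forward rate for one of the transitions 01/12/23/3CC."""
    try:
        field, _, _ = FORWARD_TRANSITIONS[transition]
    except KeyError:
        raise ValueError(
            f"unknown forward transition {transition!r}; expected one of "
            f"{sorted(FORWARD_TRANSITIONS)}"
        ) from None
    rate = float(getattr(params, field) * forward_multiplier(params, cov.dstea, cov.t2d))
    if not np.isfinite(rate):
        raise ValueError(f"non-finite forward rate for transition {transition!r}")
    return rate


def death_rate(params: ModelParameters, stage_index: int, age: float) -> float:
    """Death hazard from stage ``stage_index`` (0..5 for F0..DC) at ``age`` years."""
    if not 0 <= int(stage_index) <= 5:
        raise ValueError(f"stage_index must be 0..5, got {stage_index}")
    if age < 0:
        raise ValueError(f"negative age {age}")
    if not 18.0 <= age <= 110.0:
        warnings.warn(f"age {age} outside the plausible 18-110 range", stacklevel=2)
    return float(
        params.kdeath
        * np.exp(params.lambda_death * int(stage_index))
        * np.exp(params.k_age * (age - params.age_center))
    )


def death_rates(params: ModelParameters, ages: np.ndarray) -> np.ndarray:
    """Death hazards for all six alive stages at each age; shape ``(n, 6)``."""
    ages = np.asarray(ages, dtype=float)
    stage_fac = np.exp(params.lambda_death * np.arange(6))
    age_fac = np.exp(params.k_age * (ages - params.age_center))
    return params.kdeath * age_fac[..., None] * stage_fac


def generator_batch(
    params: ModelParameters,
    dstea: np.ndarray,
    t2d: np.ndarray,
    ages: np.ndarray,
    forward_extra: np.ndarray | None = None,
    death_extra: np.ndarray | None = None,
) -> np.ndarray:
    """Stack of intensity matrices, one per (dstea, t2d, age) triple.

    ``forward_extra``/``death_extra`` are optional additional multipliers on
    the forward rates / death hazards (used by the covariate-search
    machinery); broadcastable to the batch shape.
    """
    dstea = np.atleast_1d(np.asarray(dstea, dtype=float))
    t2d = np.atleast_1d(np.asarray(t2d, dtype=float))
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    n = max(dstea.shape[0], t2d.shape[0], ages.shape[0])
    dstea, t2d, ages = (np.broadcast_to(x, (n,)) for x in (dstea, t2d, ages))

    mult = forward_multiplier(params, dstea, t2d)
    if forward_extra is not None:
        mult = mult * forward_extra

    q = np.zeros((n, N_STATES, N_STATES))
    for field, a, b in FORWARD_TRANSITIONS.values():
        q[:, a, b] = getattr(params, field) * mult
    q[:, 4, 5] = params.kCCDC
    q[:, 1, 0] = params.kback
    q[:, 2, 1] = params.kback
    q[:, 3, 2] = params.kback
    q[:, 4, 3] = params.kCC3_fixed

    dr = death_rates(params, ages)
    if death_extra is not None:
        dr = dr * np.asarray(death_extra, dtype=float)[..., None]
    q[:, :6, 6] = dr

    idx = np.arange(N_STATES)
    q[:, idx, idx] = -q.sum(axis=2)
    return q


def build_generator(
    params: ModelParameters, cov: CovariateProfile, age: float
) -> np.ndarray:
    """7x7 transition-intensity matrix at fixed covariates and age.

    Rows sum to zero; the death row is identically zero (absorbing state).
    """
    return generator_batch(params, cov.dstea, float(cov.t2d), age)[0]


def _substep_grid(dt: float, age_step: float) -> tuple[int, float, np.ndarray]:
    """Number of sub-steps, sub-step length, and midpoint offsets for an interval."""
    n_sub = max(1, int(np.ceil(dt / age_step - 1e-12)))
    h = dt / n_sub
    mids = (np.arange(n_sub) + 0.5) * h
    return n_sub, h, mids


#: Gauss-Legendre node offset from the sub-step midpoint, in units of h
GAUSS_NODE = np.sqrt(3.0) / 6.0


def magnus_propagators(
    params: ModelParameters,
    dstea: np.ndarray,
    t2d: np.ndarray,
    ages_lo: np.ndarray,
    ages_hi: np.ndarray,
    h: np.ndarray,
    forward_extra: np.ndarray | None = None,
    death_extra: np.ndarray | None = None,
) -> np.ndarray:
    """Sub-step transition matrices of the age-inhomogeneous chain.

    Fourth-order Magnus integrator with two Gauss-Legendre nodes per
    sub-step: with ``A1 = Q(age_lo)`` and ``A2 = Q(age_hi)`` evaluated at
    the nodes ``midpoint -+ h*sqrt(3)/6``,

        P = exp( h/2 (A1 + A2) + h^2 sqrt(3)/12 [A1, A2] ),

    the transpose-convention form of the standard Magnus series, since the
    interval matrices obey the row equation ``dP/dt = P Q(t)``.  The
    commutator term has zero row sums (both generators do), so the result
    is row-stochastic to machine precision; entries can undershoot zero by
    O(h^4) in probabilities that are themselves of that order.
    """
    q1 = generator_batch(params, dstea, t2d, ages_lo, forward_extra, death_extra)
    q2 = generator_batch(params, dstea, t2d, ages_hi, forward_extra, death_extra)
    hh = np.asarray(h, dtype=float)[..., None, None]
    omega = 0.5 * hh * (q1 + q2) + (GAUSS_NODE / 2.0) * hh**2 * (q1 @ q2 - q2 @ q1)
    return expm_batch(omega)


def transition_matrix(
    params: ModelParameters,
    cov: CovariateProfile,
    age_at_start: float,
    dt: float,
    age_step: float = DEFAULT_AGE_STEP,
) -> np.ndarray:
    """Interval transition-probability matrix with age advancing over ``dt``.

    The interval is partitioned into sub-steps of length at most ``age_step``
    years; each sub-step is propagated by a fourth-order Magnus exponential
    built from the generator at two Gauss nodes around the sub-step
    midpoint, and the sub-step matrices are composed in chronological
    order.  ``dt = 0`` returns the identity.
    """
    if dt < 0:
        raise ValueError(f"negative interval length {dt}")
    if not age_step > 0:
        raise ValueError("age_step must be positive")
    if dt == 0:
        return np.eye(N_STATES)
    n_sub, h, mids = _substep_grid(dt, age_step)
    p_sub = magnus_propagators(
        params,
        np.full(n_sub, float(cov.dstea)),
        np.full(n_sub, float(cov.t2d)),
        age_at_start + mids - GAUSS_NODE * h,
        age_at_start + mids + GAUSS_NODE * h,
        np.full(n_sub, h),
    )
    p = p_sub[0]
    for k in range(1, n_sub):
        p = p @ p_sub[k]
    return np.clip(p, 0.0, None)
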