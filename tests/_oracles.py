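"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own batched matrix
exponential and likelihood recursion: transition structure is rebuilt
inline and exponentials go through ``scipy.linalg.expm``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as scipy_expm

from fibroprog import ModelParameters, PatientRecord, derive_intervals
from fibroprog.records import ObsKind


def reference_generator(
    params: ModelParameters, dstea: float, t2d: bool, age: float
) -> np.ndarray:
    """Hand-built 7x7 intensity matrix, independent of the package's."""
    mult = np.exp(params.k_DSTEA * dstea) * (1.0 + params.beta_T2D * float(t2d))
    q = np.zeros((7, 7))
    q[0, 1] = params.k01 * mult
    q[1, 2] = params.k12 * mult
    q[2, 3] = params.k23 * mult
    q[3, 4] = params.k3CC * mult
    q[4, 5] = params.kCCDC
    q[1, 0] = q[2, 1] = q[3, 2] = params.kback
    q[4, 3] = params.kCC3_fixed
    for s in range(6):
        q[s, 6] = (
            params.kdeath
            * np.exp(params.lambda_death * s)
            * np.exp(params.k_age * (age - params.age_center))
        )
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def reference_death_rates(params: ModelParameters, age: float) -> np.ndarray:
    return np.array(
        [
            params.kdeath
            * np.exp(params.lambda_death * s)
            * np.exp(params.k_age * (age - params.age_center))
            for s in range(6)
        ]
    )


def brute_force_loglik(
    record: PatientRecord, params: ModelParameters, delta: float = 1e-3
) -> float:
    """Patient log-likelihood by discrete-time matrix products.

    Time is discretized at ``delta`` years; each one-step matrix is the
    scipy matrix exponential of the intensity matrix with age frozen at the
    step midpoint.  Same observation rules as the model likelihood: staged
    biopsies condition the chain, unstaged-alive visits marginalize the
    alive states, deaths contribute the exact-time event density.
    """
    intervals = derive_intervals(record)
    f = np.zeros(7)
    f[int(record.observations[0].state)] = 1.0
    ll = 0.0
    for iv in intervals:
        n = max(1, int(np.ceil(iv.dt / delta)))
        h = iv.dt / n
        for k in range(n):
            age = iv.age_start + (k + 0.5) * h
            q = reference_generator(params, iv.dstea, iv.t2d, age)
            f = f @ scipy_expm(q * h)
        if iv.end_kind is ObsKind.STAGE:
            lik = f[iv.end_state]
            f = np.zeros(7)
            f[iv.end_state] = 1.0
        elif iv.end_kind is ObsKind.ALIVE_UNSTAGED:
            lik = f[:6].sum()
            f = np.concatenate([f[:6] / lik, [0.0]])
        else:
            age_end = iv.age_start + iv.dt
            lik = float(f[:6] @ reference_death_rates(params, age_end))
        if not lik > 0:
            return -np.inf
        ll += np.log(lik)
    return float(ll)


def reference_transition_matrix(
    params: ModelParameters,
    dstea: float,
    t2d: bool,
    age_start: float,
    dt: float,
    n_steps: int = 400,
) -> np.ndarray:
    """Interval transition probabilities by fine scipy-expm composition."""
    h = dt / n_steps
    p = np.eye(7)
    for k in range(n_steps):
        age = age_start + (k + 0.5) * h
        p = p @ scipy_expm(reference_generator(params, dstea, t2d, age) * h)
    return p
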