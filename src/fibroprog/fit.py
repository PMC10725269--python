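"""Maximum-likelihood estimation, bootstrap intervals, and the stepwise
likelihood-ratio covariate search.

Rates are optimized on the log scale (positivity by construction) and the
T2D effect as ``log(1 + beta_T2D)`` (lower bound -1); the remaining
coefficients are unconstrained.  Optimization runs a short derivative-free
simplex from the supplied start followed by a quasi-Newton (L-BFGS-B)
polish with finite-difference gradients.  Relative standard errors are
obtained from the inverse of the numerically differentiated Hessian on the
transformed scale and mapped to the natural scale by the delta method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import CovariateSpec, LikelihoodPlan
from .params import RATE_FIELDS, ModelParameters, free_parameters

logger = logging.getLogger(__name__)

_EXT_NAME = "_theta_cov"  # synthetic name of a searched covariate coefficient
_BIG = 1e12  # penalty objective outside the likelihood's support


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    estimates: ModelParameters
    log_likelihood: float
    converged: bool
    n_patients: int
    n_intervals: int
    free: list[str]
    rse: dict[str, float] | None = None
    se_message: str | None = None
    theta_cov: float | None = None
    n_evaluations: int = 0
    optimizer_message: str = ""

    def to_dict(self) -> dict:
        out = {
            "estimates": self.estimates.to_dict(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_patients": self.n_patients,
            "n_intervals": self.n_intervals,
            "free": list(self.free),
            "rse": self.rse,
            "se_message": self.se_message,
            "n_evaluations": self.n_evaluations,
            "optimizer_message": self.optimizer_message,
        }
        if self.theta_cov is not None:
            out["theta_cov"] = self.theta_cov
        return out


def _to_internal(name: str, value: float) -> float:
    if name in RATE_FIELDS:
        return float(np.log(max(value, 1e-12)))
    if name == "beta_T2D":
        return float(np.log1p(max(value, -0.999)))
    return float(value)


def _from_internal(name: str, x: float) -> float:
    if name in RATE_FIELDS:
        return float(np.exp(x))
    if name == "beta_T2D":
        return float(np.expm1(x))
    return float(x)


def _unpack(
    x: np.ndarray, free: list[str], base: ModelParameters
) -> tuple[ModelParameters, float | None]:
    changes = {}
    theta = None
    for name, xi in zip(free, x):
        if name == _EXT_NAME:
            theta = float(xi)
        else:
            changes[name] = _from_internal(name, float(xi))
    return base.replace(**changes), theta


def fit_mle(
    records: Sequence,
    init: ModelParameters | None = None,
    fixed: Sequence[str] = (),
    *,
    age_step: float = 0.5,
    dstea_convention: str = "carry_forward",
    extension: CovariateSpec | None = None,
    ext_init: float = 0.0,
    compute_se: bool = True,
    simplex_maxfev: int = 150,
    maxfun: int = 4000,
    ftol: float = 1e-9,
) -> FitResult:
    """Fit the model to interval-censored records by maximum likelihood.

    Parameters not listed in ``fixed`` are estimated; ``kCC3_fixed`` and the
    age-centering constant are always held at their values in ``init``.
    ``extension`` adds a single searched covariate coefficient (starting at
    ``ext_init``) on top of the base model.  Non-convergence is reported via
    ``FitResult.converged``, never as an exception; a Hessian that is not
    positive definite yields estimates without standard errors.
    """
    init = init if init is not None else ModelParameters()
    free = free_parameters(fixed)
    plan = LikelihoodPlan(
        records,
        age_step=age_step,
        dstea_convention=dstea_convention,
        extension=extension,
    )
    names = list(free) + ([_EXT_NAME] if extension is not None else [])
    x0 = np.array(
        [ext_init if n == _EXT_NAME else _to_internal(n, getattr(init, n)) for n in names]
    )

    n_eval = 0

    def nll(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            params, theta = _unpack(x, names, init)
        except ValueError:
            return _BIG
        ll = plan.loglik(params, theta)
        if not np.isfinite(ll):
            return _BIG
        return -ll

    x = x0
    if simplex_maxfev > 0 and len(names) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nm = optimize.minimize(
                nll,
                x,
                method="Nelder-Mead",
                options={"maxfev": simplex_maxfev, "xatol": 1e-4, "fatol": 1e-6},
            )
        x = nm.x
    res = optimize.minimize(
        nll,
        x,
        method="L-BFGS-B",
        options={"maxfun": maxfun, "ftol": ftol, "gtol": 1e-6, "eps": 1e-6},
    )
    if nll(res.x) > nll(x):  # pathological line-search exit; keep the better point
        res.x, res.fun = x, nll(x)
    converged = bool(res.success)
    if not converged and res.fun < _BIG / 2:
        # line-search aborts are common with finite-difference gradients;
        # verify the point with a simplex polish and accept it if no
        # meaningful improvement remains
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            polish = optimize.minimize(
                nll,
                res.x,
                method="Nelder-Mead",
                options={"maxfev": 200 * len(names), "fatol": 1e-7, "xatol": 1e-7},
            )
        if polish.fun < res.fun:
            res.x, res.fun = polish.x, polish.fun
        converged = bool(polish.success)

    params_hat, theta_hat = _unpack(res.x, names, init)
    ll_hat = -float(res.fun)
    converged = converged and np.isfinite(ll_hat) and res.fun < _BIG / 2
    if not converged:
        logger.warning("optimizer did not converge: %s", res.message)

    rse = None
    se_message = None
    if compute_se and converged:
        rse, se_message = _rse_from_hessian(nll, res.x, names, params_hat)
    elif compute_se:
        se_message = "no standard errors: optimizer did not converge"

    return FitResult(
        estimates=params_hat,
        log_likelihood=ll_hat,
        converged=converged,
        n_patients=plan.n_patients,
        n_intervals=plan.n_intervals,
        free=names,
        rse=rse,
        se_message=se_message,
        theta_cov=theta_hat,
        n_evaluations=n_eval,
        optimizer_message=str(res.message),
    )


def _rse_from_hessian(
    nll, x: np.ndarray, names: list[str], params: ModelParameters
) -> tuple[dict[str, float] | None, str | None]:
    """Relative standard errors from a central-difference Hessian of the
    negative log-likelihood on the transformed scale."""
    n = len(x)
    h = 1e-4 * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    f0 = nll(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        hess[i, i] = (nll(x + ei) - 2 * f0 + nll(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            fij = nll(x + ei + ej) - nll(x + ei - ej) - nll(x - ei + ej) + nll(x - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * h[i] * h[j])
    try:
        np.linalg.cholesky(hess)
    except np.linalg.LinAlgError:
        return None, "no standard errors: Hessian not positive definite"
    cov = np.linalg.inv(hess)
    var = np.diag(cov)
    rse: dict[str, float] = {}
    for i, name in enumerate(names):
        se_int = float(np.sqrt(var[i]))
        if name in RATE_FIELDS:
            rse[name] = se_int  # SE of log(rate) equals SE/estimate by delta method
        elif name == "beta_T2D":
            beta = params.beta_T2D
            rse[name] = se_int * (1.0 + beta) / abs(beta) if beta != 0 else np.inf
        elif name == _EXT_NAME:
            rse[name] = se_int  # searched coefficient: absolute SE
        else:
            value = getattr(params, name)
            rse[name] = se_int / abs(value) if value != 0 else np.inf
    return rse, None


def bootstrap_ci(
    records: Sequence,
    n_boot: int,
    level: float = 90.0,
    seed: int | None = None,
    init: ModelParameters | None = None,
    fixed: Sequence[str] = (),
    **fit_kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap confidence intervals from patient resampling.

    Patients are resampled with replacement ``n_boot`` times and each
    replicate refit (initialized at the full-data estimates); replicates
    that fail to converge are dropped and counted, with a warning when more
    than 5% are lost.  Returns a table with the full-data estimate, the
    bootstrap mean, and the percentile interval at ``level``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if not 0 < level < 100:
        raise ValueError("level must be a percentage in (0, 100)")
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("compute_se", False)

    full = fit_mle(records, init=init, fixed=fixed, **fit_kwargs)
    free = [n for n in full.free if n != _EXT_NAME]
    n = len(records)
    draws: list[dict[str, float]] = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [records[i] for i in idx]
        try:
            fit = fit_mle(sample, init=full.estimates, fixed=fixed, **fit_kwargs)
        except ValueError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        draws.append({k: getattr(fit.estimates, k) for k in free})
    if n_failed > 0.05 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap replicates dropped (non-convergence)",
            stacklevel=2,
        )
    if not draws:
        raise RuntimeError("all bootstrap replicates failed to converge")
    tab = pd.DataFrame(draws)
    alpha = (100.0 - level) / 2.0
    out = pd.DataFrame(
        {
            "parameter": free,
            "estimate": [getattr(full.estimates, k) for k in free],
            "boot_mean": tab.mean().reindex(free).to_numpy(),
            "ci_lo": tab.quantile(alpha / 100.0).reindex(free).to_numpy(),
            "ci_hi": tab.quantile(1 - alpha / 100.0).reindex(free).to_numpy(),
        }
    )
    out.attrs["n_boot"] = n_boot
    out.attrs["n_failed"] = n_failed
    out.attrs["level"] = level
    return out


@dataclass(frozen=True)
class LRTStep:
    """Outcome of one stepwise covariate test (df = 1)."""

    p_value: float
    include: bool
    loglik_base: float
    loglik_extended: float
    theta: float | None
    direction: str
    note: str = ""


def lrt_covariate_step(
    records: Sequence,
    candidate: CovariateSpec,
    direction: str = "forward",
    *,
    init: ModelParameters | None = None,
    fixed: Sequence[str] = (),
    alpha_forward: float = 0.05,
    alpha_backward: float = 0.01,
    **fit_kwargs,
) -> LRTStep:
    """One step of the stepwise covariate search.

    Fits the base model and the model extended by ``candidate`` (one added
    parameter) and compares them with a likelihood-ratio test on one degree
    of freedom.  Forward inclusion uses ``alpha_forward`` (0.05); backward
    elimination retains the covariate only at the stricter
    ``alpha_backward`` (0.01).  A non-convergent extended fit rejects the
    step with a warning.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    fit_kwargs.setdefault("compute_se", False)
    base = fit_mle(records, init=init, fixed=fixed, **fit_kwargs)
    ext = fit_mle(records, init=init, fixed=fixed, extension=candidate, **fit_kwargs)
    if not ext.converged or not base.converged:
        warnings.warn(
            f"covariate step for {candidate.name!r} rejected: fit did not converge",
            stacklevel=2,
        )
        return LRTStep(
            p_value=1.0,
            include=False,
            loglik_base=base.log_likelihood,
            loglik_extended=ext.log_likelihood,
            theta=ext.theta_cov,
            direction=direction,
            note="non-convergent fit",
        )
    lr = max(0.0, 2.0 * (ext.log_likelihood - base.log_likelihood))
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    alpha = alpha_forward if direction == "forward" else alpha_backward
    return LRTStep(
        p_value=p,
        include=bool(p < alpha),
        loglik_base=base.log_likelihood,
        loglik_extended=ext.log_likelihood,
        theta=ext.theta_cov,
        direction=direction,
    )
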