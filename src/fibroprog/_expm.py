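"""Batched matrix exponential.

The interval-censored likelihood needs the exponential of tens of thousands
of small (7x7) intensity matrices per evaluation; calling a general-purpose
routine one matrix at a time dominates the run time.  This module evaluates
a degree-12 Taylor polynomial (Paterson-Stockmeyer form, five batched
matrix products, no linear solve) after scaling each matrix to 1-norm at
most 1/2, then squares back per matrix.  At that norm the truncation error
of the degree-12 polynomial is ~2e-14, well below the accumulated rounding
of any subsequent computation, and the sub-step intensity matrices this is
used on rarely need scaling at all.
"""

from __future__ import annotations

import math

import numpy as np

_THETA = 0.5  # scale target: degree-12 truncation error ~2e-14 at this 1-norm
_INV_FACT = [1.0 / math.factorial(k) for k in range(13)]


def expm_batch(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of square matrices.

    Parameters
    ----------
    a : ndarray, shape (..., n, n)

    Returns
    -------
    ndarray of the same shape, ``expm`` applied to each trailing matrix.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected (..., n, n) array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite entries in matrix exponential input")

    norms = np.abs(a).sum(axis=-2).max(axis=-1)  # 1-norm of each matrix
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(norms / _THETA))
    s = np.where(norms > _THETA, s, 0.0).astype(int)
    if s.ndim == 0:
        s = s[None]
        a = a[None]
        squeeze = True
    else:
        squeeze = False
    a = a * (0.5**s)[..., None, None]

    c = _INV_FACT
    ident = np.broadcast_to(np.eye(a.shape[-1]), a.shape)
    a2 = a @ a
    a3 = a2 @ a
    a4 = a2 @ a2
    # b_k = sum_j C[k, j] * {I, A, A2, A3}_j as one GEMM over the flattened stack
    powers = np.stack([np.ascontiguousarray(ident), a, a2, a3]).reshape(4, -1)
    cmat = np.array(c[:12], dtype=float).reshape(3, 4)
    b0, b1, b2 = (cmat @ powers).reshape(3, *a.shape)
    p = ((c[12] * a4 + b2) @ a4 + b1) @ a4 + b0

    flat_s = s.reshape(-1)
    flat_p = p.reshape(-1, a.shape[-1], a.shape[-1])
    for k in range(int(flat_s.max(initial=0))):
        sel = flat_s > k
        flat_p[sel] = flat_p[sel] @ flat_p[sel]
    p = flat_p.reshape(p.shape)
    return p[0] if squeeze else p
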