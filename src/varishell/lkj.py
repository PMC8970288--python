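"""Unconstrained parameterisation of correlation matrices with an LKJ prior.

A K x K correlation matrix is represented by K(K-1)/2 unconstrained numbers
via the canonical-partial-correlation construction of its Cholesky factor
(tanh to map the reals onto (-1, 1), rows filled so that each row of L has
unit norm).  The LKJ(eta) log-density on the Cholesky factor and the
log-absolute-determinant of the transform are accumulated along the forward
pass, so an unconstrained sampler explores exactly the LKJ distribution.

Gradients are obtained by complex-step differentiation of the forward pass
(machine-precision accurate; the transform is analytic), batched over the
K(K-1)/2 coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_corr_params",
    "chol_corr",
    "chol_corr_with_grad",
    "chol_corr_forward",
    "chol_corr_backward",
]

_H = 1e-20  # complex-step size; below sqrt precision of any quantity involved


def n_corr_params(k: int) -> int:
    return k * (k - 1) // 2


def _forward(y: np.ndarray, k: int, eta: float):
    """Forward transform.  ``y`` may be complex and carry a leading batch axis.

    Returns (L, logp) where L is the Cholesky factor (batched) and logp is the
    LKJ(eta) log-density of L plus the transform's log-|Jacobian|.
    """
    batched = y.ndim == 2
    ys = y if batched else y[None, :]
    b = ys.shape[0]
    L = np.zeros((b, k, k), dtype=ys.dtype)
    L[:, 0, 0] = 1.0
    logp = np.zeros(b, dtype=ys.dtype)
    idx = 0
    for i in range(1, k):
        log_rem = np.zeros(b, dtype=ys.dtype)
        for j in range(i):
            yi = ys[:, idx]
            idx += 1
            # log(1 - tanh^2 y) = -2 log cosh y, in overflow-safe form; the
            # sign switch follows the real part, each branch being exact, so
            # complex-step perturbations differentiate correctly.
            sgn = np.where(np.real(yi) >= 0, 1.0, -1.0)
            log_cosh = sgn * yi + np.log1p(np.exp(-2.0 * sgn * yi)) - np.log(2.0)
            log_omr2 = -2.0 * log_cosh
            L[:, i, j] = np.tanh(yi) * np.exp(0.5 * log_rem)
            # d L[i,j] / d y = (1 - r^2) * sqrt(rem): triangular Jacobian
            logp = logp + log_omr2 + 0.5 * log_rem
            log_rem = log_rem + log_omr2
        L[:, i, i] = np.exp(0.5 * log_rem)
        # LKJ(eta) density on the Cholesky factor (Stan convention):
        # sum over rows i>=1 of (K - (i+1) + 2*eta - 2) * log L[i,i]
        logp = logp + (k - (i + 1) + 2.0 * eta - 2.0) * 0.5 * log_rem
    if not batched:
        return L[0], logp[0]
    return L, logp


def chol_corr(y: np.ndarray, k: int, eta: float = 2.0) -> tuple[np.ndarray, float]:
    """Cholesky factor of the correlation matrix and its prior+Jacobian logp."""
    L, logp = _forward(np.asarray(y, dtype=float), k, eta)
    return L, float(logp)


def chol_corr_forward(y: np.ndarray, k: int, eta: float = 2.0):
    """Real forward pass that also returns the cache for the backward pass.

    Returns (L, logp, cache); ``logp`` is the LKJ(eta) log-density plus the
    transform log-|Jacobian| as in :func:`chol_corr`.
    """
    y = np.asarray(y, dtype=float)
    L = np.zeros((k, k))
    L[0, 0] = 1.0
    logp = 0.0
    r = np.tanh(y)
    idx = 0
    log_rem_cache = np.empty(len(y))  # log_rem *before* consuming y[idx]
    for i in range(1, k):
        log_rem = 0.0
        for j in range(i):
            log_omr2 = -2.0 * (np.abs(y[idx]) + np.log1p(np.exp(-2.0 * np.abs(y[idx]))) - np.log(2.0))
            log_rem_cache[idx] = log_rem
            L[i, j] = r[idx] * np.exp(0.5 * log_rem)
            logp += log_omr2 + 0.5 * log_rem
            log_rem += log_omr2
            idx += 1
        L[i, i] = np.exp(0.5 * log_rem)
        logp += (k - (i + 1) + 2.0 * eta - 2.0) * 0.5 * log_rem
    return L, float(logp), (y, r, log_rem_cache, k, eta, L)


def chol_corr_backward(cache, grad_L: np.ndarray) -> np.ndarray:
    """Gradient wrt y of ``logp + <grad_L, L>`` given the forward cache.

    Matches the complex-step result to machine precision (asserted in
    tests); runs in one reverse sweep.
    """
    y, r, log_rem_cache, k, eta, L = cache
    g = np.empty(len(y))
    idx = len(y)
    for i in range(k - 1, 0, -1):
        coeff = k - (i + 1) + 2.0 * eta - 2.0
        # d(total)/d log_rem_final for this row: diag term of L and of logp
        grem_next = 0.5 * grad_L[i, i] * L[i, i] + 0.5 * coeff
        for j in range(i - 1, -1, -1):
            idx -= 1
            s_rem = np.exp(0.5 * log_rem_cache[idx])
            # lo_j feeds logp directly (weight 1) and log_rem downstream
            g_lo = 1.0 + grem_next
            g[idx] = grad_L[i, j] * s_rem * (1.0 - r[idx] ** 2) - 2.0 * r[idx] * g_lo
            # log_rem_j feeds: logp (0.5), L[i,j] (0.5 L), and log_rem_{j+1}
            grem_next = 0.5 + 0.5 * grad_L[i, j] * L[i, j] + grem_next
    return g


def chol_corr_with_grad(
    y: np.ndarray, k: int, grad_L: np.ndarray, eta: float = 2.0
) -> tuple[np.ndarray, float, np.ndarray]:
    """Forward transform plus the pullback of a downstream gradient.

    Given d(loglik)/dL in ``grad_L`` (full lower triangle, diagonal included),
    returns (L, logp, g) with ``g = d(logp + <grad_L, L>)/dy`` — i.e. the
    total gradient contribution of this correlation block to the
    unconstrained posterior gradient.
    """
    y = np.asarray(y, dtype=float)
    m = len(y)
    batch = y[None, :] + 1j * _H * np.eye(m)
    L_b, logp_b = _forward(batch, k, eta)
    L = L_b[0].real
    logp = float(logp_b[0].real)
    # chain rule via the imaginary parts of each perturbed forward pass
    g = logp_b.imag / _H + np.einsum("ij,bij->b", grad_L, L_b.imag) / _H
    return L, logp, g
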