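"""Hamiltonian Monte Carlo with dual-averaging step size and diagonal mass
adaptation.

A compact, dependency-free NUTS-style workhorse for the posteriors in this
package: static-trajectory HMC with jittered path length (guards against
resonance), Stan-like warmup windows (initial step-size phase, doubling
variance-estimation windows that refresh the diagonal mass matrix, final
step-size phase), and a divergence counter based on the energy error.

The target density must supply ``logp_and_grad(theta) -> (float, ndarray)``
on the unconstrained scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMCSettings", "HMCChain", "sample_chain", "sample_chains"]


@dataclass(frozen=True)
class HMCSettings:
    n_warmup: int = 1000
    n_draws: int = 1000
    target_accept: float = 0.9
    integration_time: float = 1.2  # nominal trajectory length (time units)
    max_leapfrog: int = 128
    init_step_size: float = 0.1
    divergence_energy: float = 1000.0
    jitter: tuple[float, float] = (0.7, 1.3)


@dataclass
class HMCChain:
    draws: np.ndarray  # (n_draws, dim)
    accept_rate: float
    divergences: int
    step_size: float
    inv_mass: np.ndarray
    logp: np.ndarray = field(default=None)


def _leapfrog(logp_and_grad, theta, p, grad, eps, n_steps, inv_mass):
    for _ in range(n_steps):
        p = p + 0.5 * eps * grad
        theta = theta + eps * inv_mass * p
        logp, grad = logp_and_grad(theta)
        if not np.isfinite(logp):
            return theta, p, logp, grad
        p = p + 0.5 * eps * grad
    return theta, p, logp, grad


def sample_chain(
    logp_and_grad,
    theta0: np.ndarray,
    settings: HMCSettings,
    rng: np.random.Generator,
) -> HMCChain:
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    logp, grad = logp_and_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log-density at the initial point")

    inv_mass = np.ones(dim)
    eps = settings.init_step_size

    # dual averaging state (Hoffman & Gelman defaults)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    n_warm = settings.n_warmup
    # Stan-like windows: 15% step size, then doubling covariance windows, 10% tail
    init_buffer = max(1, int(0.15 * n_warm))
    term_buffer = max(1, int(0.10 * n_warm))
    window_start = init_buffer
    window_len = max(10, int(0.25 * (n_warm - init_buffer - term_buffer)))
    windows = []
    start = window_start
    while start + window_len < n_warm - term_buffer:
        windows.append((start, start + window_len))
        start += window_len
        window_len *= 2
    if windows:
        windows[-1] = (windows[-1][0], n_warm - term_buffer)
    elif n_warm - term_buffer > window_start:
        windows = [(window_start, n_warm - term_buffer)]
    window_samples: list[np.ndarray] = []
    window_idx = 0

    draws = np.empty((settings.n_draws, dim))
    logps = np.empty(settings.n_draws)
    divergences = 0
    n_accept, n_total = 0, 0

    total_iters = n_warm + settings.n_draws
    for it in range(total_iters):
        warmup = it < n_warm
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - 0.5 * np.sum(inv_mass * p * p)
        n_steps = int(
            np.clip(
                np.ceil(settings.integration_time / eps * rng.uniform(*settings.jitter)),
                1,
                settings.max_leapfrog,
            )
        )
        theta_new, p_new, logp_new, grad_new = _leapfrog(
            logp_and_grad, theta, p, grad, eps, n_steps, inv_mass
        )
        if np.isfinite(logp_new):
            joint_new = logp_new - 0.5 * np.sum(inv_mass * p_new * p_new)
            delta = joint_new - joint0
        else:
            delta = -np.inf
        accept_prob = min(1.0, np.exp(min(delta, 0.0)))
        diverged = (not np.isfinite(delta)) or (-delta > settings.divergence_energy)
        if diverged and not warmup:
            divergences += 1
        if (not diverged) and rng.uniform() < accept_prob:
            theta, logp, grad = theta_new, logp_new, grad_new
            if not warmup:
                n_accept += 1
        if not warmup:
            n_total += 1

        if warmup:
            # dual averaging step-size update (counter restarts with each metric)
            da_count += 1
            m = da_count
            h_bar = (1 - 1 / (m + t0)) * h_bar + (settings.target_accept - accept_prob) / (
                m + t0
            )
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # mass-matrix windows
            if window_idx < len(windows):
                lo, hi = windows[window_idx]
                if lo <= it < hi:
                    window_samples.append(theta.copy())
                if it == hi - 1 and window_samples:
                    var = np.var(np.asarray(window_samples), axis=0)
                    n_s = len(window_samples)
                    # regularised like Stan: shrink toward unit scale
                    inv_mass = (n_s / (n_s + 5.0)) * var + (5.0 / (n_s + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-8)
                    window_samples = []
                    window_idx += 1
                    # restart step-size adaptation for the new metric
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
                    da_count = 0
            if it == n_warm - 1:
                eps = float(np.exp(log_eps_bar)) if log_eps_bar != 0.0 else eps
        else:
            draws[it - n_warm] = theta
            logps[it - n_warm] = logp

    return HMCChain(
        draws=draws,
        accept_rate=n_accept / max(n_total, 1),
        divergences=divergences,
        step_size=eps,
        inv_mass=inv_mass,
        logp=logps,
    )


def sample_chains(
    logp_and_grad,
    init_fn,
    n_chains: int,
    settings: HMCSettings,
    seed: int,
) -> list[HMCChain]:
    """Run ``n_chains`` independent chains; ``init_fn(rng) -> theta0``."""
    chains = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_chains):
        rng = np.random.default_rng(child)
        chains.append(sample_chain(logp_and_grad, init_fn(rng), settings, rng))
    return chains
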