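"""No-U-Turn Sampler (NUTS) with dual-averaging adaptation.

A self-contained implementation of the dynamic Hamiltonian Monte Carlo
variant of Hoffman & Gelman (slice formulation): trajectories are doubled
until the no-U-turn criterion fires, the next state is drawn uniformly
from the accepted slice states, the step size is tuned during warmup by
dual averaging toward a target acceptance statistic, and a diagonal mass
matrix is estimated from the first warmup half. The target density is
supplied as a callable returning the log density and its gradient, so
any continuously differentiable unconstrained posterior can be sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "nuts_sample", "split_rhat"]

DELTA_MAX = 1000.0  # energy-error threshold flagging a divergent trajectory


@dataclass
class NutsResult:
    """Draws and diagnostics from one NUTS chain."""

    samples: np.ndarray  # (n_samples, dim)
    step_size: float
    n_divergent: int
    accept_rate: float


def _find_initial_step(logp_grad, theta, inv_mass, rng) -> float:
    """Heuristic step-size initialization: double/halve until the one-step
    acceptance probability crosses 1/2."""
    eps = 1.0
    logp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    joint0 = logp - 0.5 * np.sum(inv_mass * r**2)
    theta1, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    joint1 = logp1 - 0.5 * np.sum(inv_mass * r1**2)
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        theta1, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        joint1 = logp1 - 0.5 * np.sum(inv_mass * r1**2)
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    return eps


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int = 500,
    n_samples: int = 500,
    seed: int | np.random.Generator = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.9,
) -> NutsResult:
    """Run one NUTS chain from ``theta0``.

    Warmup adapts the step size throughout and replaces the unit diagonal
    mass matrix with regularized sample variances halfway through
    (restarting step-size adaptation); only post-warmup draws are
    returned.
    """
    rng = np.random.default_rng(seed)
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    half = n_warmup // 2
    warmup_buffer = []
    samples = np.empty((n_samples, dim))
    n_divergent = 0
    accept_sum, accept_count = 0.0, 0

    logp, grad = logp_grad(theta)

    for it in range(n_warmup + n_samples):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        joint0 = logp - 0.5 * np.sum(inv_mass * r0**2)
        log_u = joint0 + np.log(rng.uniform())

        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_next, logp_next, grad_next = theta, logp, grad
        n_valid, keep_going = 1, True
        alpha_sum, n_alpha = 0.0, 0
        divergent = False
        depth = 0

        while keep_going and depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                (
                    _, _, _, theta_plus, r_plus, grad_plus,
                    theta_prop, logp_prop, grad_prop,
                    n_prime, s_prime, a_sum, n_a, div,
                ) = _build_tree(
                    logp_grad, theta_plus, r_plus, grad_plus,
                    log_u, direction, depth, eps, inv_mass, joint0, rng,
                )
            else:
                (
                    theta_minus, r_minus, grad_minus, _, _, _,
                    theta_prop, logp_prop, grad_prop,
                    n_prime, s_prime, a_sum, n_a, div,
                ) = _build_tree(
                    logp_grad, theta_minus, r_minus, grad_minus,
                    log_u, direction, depth, eps, inv_mass, joint0, rng,
                )
            divergent = divergent or div
            if s_prime and n_prime > 0:
                if rng.uniform() < n_prime / max(n_valid, 1):
                    theta_next, logp_next, grad_next = theta_prop, logp_prop, grad_prop
            n_valid += n_prime
            alpha_sum += a_sum
            n_alpha += n_a
            span = theta_plus - theta_minus
            keep_going = (
                s_prime
                and np.dot(span, inv_mass * r_minus) >= 0
                and np.dot(span, inv_mass * r_plus) >= 0
            )
            depth += 1

        theta, logp, grad = theta_next, logp_next, grad_next
        alpha = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            weight = adapt_iter**-kappa
            log_eps_bar = weight * log_eps + (1 - weight) * log_eps_bar
            eps = float(np.exp(log_eps))
            warmup_buffer.append(theta.copy())
            if it == half and len(warmup_buffer) > 10:
                window = np.asarray(warmup_buffer[len(warmup_buffer) // 2 :])
                var = window.var(axis=0, ddof=1)
                n_w = window.shape[0]
                # Stan-style shrinkage toward unit variance
                inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-10)
                eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            samples[it - n_warmup] = theta
            n_divergent += int(divergent)
            accept_sum += alpha
            accept_count += 1

    return NutsResult(
        samples=samples,
        step_size=eps,
        n_divergent=n_divergent,
        accept_rate=accept_sum / max(accept_count, 1),
    )


def _build_tree(
    logp_grad, theta, r, grad, log_u, direction, depth, eps, inv_mass, joint0, rng
):
    """Recursively double the trajectory; returns edge states, a proposal
    drawn uniformly from the slice-valid states, counts and flags."""
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(
            logp_grad, theta, r, grad, direction * eps, inv_mass
        )
        joint = logp1 - 0.5 * np.sum(inv_mass * r1**2)
        if not np.isfinite(joint):
            joint = -np.inf
        n_prime = int(log_u <= joint)
        divergent = log_u - DELTA_MAX > joint
        alpha = min(1.0, np.exp(min(joint - joint0, 0.0)))
        return (
            theta1, r1, grad1, theta1, r1, grad1,
            theta1, logp1, grad1,
            n_prime, not divergent, alpha, 1, divergent,
        )

    (
        theta_minus, r_minus, grad_minus, theta_plus, r_plus, grad_plus,
        theta_prop, logp_prop, grad_prop,
        n1, s1, a1, na1, div1,
    ) = _build_tree(
        logp_grad, theta, r, grad, log_u, direction, depth - 1, eps, inv_mass, joint0, rng
    )
    div2 = False
    if s1:
        if direction == 1:
            (
                _, _, _, theta_plus, r_plus, grad_plus,
                theta_prop2, logp_prop2, grad_prop2,
                n2, s2, a2, na2, div2,
            ) = _build_tree(
                logp_grad, theta_plus, r_plus, grad_plus,
                log_u, direction, depth - 1, eps, inv_mass, joint0, rng,
            )
        else:
            (
                theta_minus, r_minus, grad_minus, _, _, _,
                theta_prop2, logp_prop2, grad_prop2,
                n2, s2, a2, na2, div2,
            ) = _build_tree(
                logp_grad, theta_minus, r_minus, grad_minus,
                log_u, direction, depth - 1, eps, inv_mass, joint0, rng,
            )
        if n2 > 0 and rng.uniform() < n2 / max(n1 + n2, 1):
            theta_prop, logp_prop, grad_prop = theta_prop2, logp_prop2, grad_prop2
        span = theta_plus - theta_minus
        s1 = (
            s2
            and np.dot(span, inv_mass * r_minus) >= 0
            and np.dot(span, inv_mass * r_plus) >= 0
        )
        n1 += n2
        a1 += a2
        na1 += na2
    return (
        theta_minus, r_minus, grad_minus, theta_plus, r_plus, grad_plus,
        theta_prop, logp_prop, grad_prop,
        n1, s1, a1, na1, div1 or div2,
    )


def split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split Gelman-Rubin statistic per parameter.

    ``chains`` has shape (n_chains, n_draws, dim); each chain is split in
    half, and the classic between/within variance ratio is computed on
    the resulting half-chains.
    """
    n_chains, n_draws, dim = chains.shape
    half = n_draws // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    halves = np.concatenate([chains[:, :half, :], chains[:, half : 2 * half, :]], axis=0)
    m, n = halves.shape[0], halves.shape[1]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return np.where(w <= 1e-300, 1.0, rhat)
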