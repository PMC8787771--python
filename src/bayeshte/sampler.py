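"""Adaptive No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

This is the MCMC engine behind every model fit in the package.  It implements
the HMC-family contract the analyses assume: multiple independent chains, a
warm-up phase that adapts the integrator step size (dual averaging towards a
target acceptance statistic) and a diagonal mass matrix (posterior-variance
estimate from warm-up draws), post-warm-up draws with frozen tuning, and a
divergence count per chain (leapfrog trajectories whose Hamiltonian error
exceeds a fixed threshold).

The target density is supplied as a callable returning the joint log density
and its gradient on the unconstrained scale; constrained parameters (scales)
are handled by the model layer via log transforms with Jacobian terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nuts_sample", "NutsResult"]

# Hamiltonian error beyond which a trajectory is declared divergent.
_DIVERGENCE_THRESHOLD = 1000.0
_MAX_TREEDEPTH = 10


@dataclass
class NutsResult:
    """Raw sampler output: draws shaped (chains, draws, dim) plus tuning info."""

    draws: np.ndarray
    divergences: np.ndarray  # per-chain divergence counts (post-warm-up)
    step_sizes: np.ndarray  # final adapted step size per chain
    inv_mass: np.ndarray  # per-chain diagonal inverse mass


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def _find_reasonable_epsilon(logp_grad, q0, inv_mass, rng):
    """Heuristic initial step size: double/halve until acceptance crosses 0.5."""
    eps = 1.0
    logp0, grad0 = logp_grad(q0)
    p0 = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    h0 = logp0 - 0.5 * np.sum(inv_mass * p0 * p0)
    q, p, logp, _ = _leapfrog(logp_grad, q0, p0, grad0, eps, inv_mass)
    h = logp - 0.5 * np.sum(inv_mass * p * p)
    if not np.isfinite(h):
        h = -np.inf
    direction = 1.0 if (h - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q, p, logp, _ = _leapfrog(logp_grad, q0, p0, grad0, eps, inv_mass)
        h = logp - 0.5 * np.sum(inv_mass * p * p)
        if not np.isfinite(h):
            h = -np.inf
        if direction * (h - h0) < direction * np.log(0.5):
            break
    return max(eps, 1e-10)


class _TreeState:
    __slots__ = (
        "q_minus", "p_minus", "grad_minus",
        "q_plus", "p_plus", "grad_plus",
        "q_prop", "logp_prop", "grad_prop",
        "n_valid", "keep_going", "sum_alpha", "n_alpha", "diverged",
    )


def _build_tree(logp_grad, q, p, grad, log_u, direction, depth, eps, inv_mass,
                h0, rng):
    """Recursively double the trajectory; slice-sampler variant of NUTS."""
    if depth == 0:
        st = _TreeState()
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        h1 = logp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(h1):
            h1 = -np.inf
        st.q_minus = st.q_plus = st.q_prop = q1
        st.p_minus = st.p_plus = p1
        st.grad_minus = st.grad_plus = st.grad_prop = grad1
        st.logp_prop = logp1
        st.n_valid = int(log_u <= h1)
        st.diverged = (h0 - h1) > _DIVERGENCE_THRESHOLD if np.isfinite(h1) else True
        st.keep_going = not st.diverged
        st.sum_alpha = float(np.exp(min(0.0, h1 - h0))) if np.isfinite(h1) else 0.0
        st.n_alpha = 1
        return st

    st1 = _build_tree(logp_grad, q, p, grad, log_u, direction, depth - 1, eps,
                      inv_mass, h0, rng)
    if st1.keep_going:
        if direction == -1:
            st2 = _build_tree(logp_grad, st1.q_minus, st1.p_minus, st1.grad_minus,
                              log_u, direction, depth - 1, eps, inv_mass, h0, rng)
            st1.q_minus, st1.p_minus, st1.grad_minus = st2.q_minus, st2.p_minus, st2.grad_minus
        else:
            st2 = _build_tree(logp_grad, st1.q_plus, st1.p_plus, st1.grad_plus,
                              log_u, direction, depth - 1, eps, inv_mass, h0, rng)
            st1.q_plus, st1.p_plus, st1.grad_plus = st2.q_plus, st2.p_plus, st2.grad_plus
        total = st1.n_valid + st2.n_valid
        if total > 0 and rng.random() < st2.n_valid / total:
            st1.q_prop, st1.logp_prop, st1.grad_prop = st2.q_prop, st2.logp_prop, st2.grad_prop
        st1.n_valid = total
        st1.sum_alpha += st2.sum_alpha
        st1.n_alpha += st2.n_alpha
        st1.diverged = st1.diverged or st2.diverged
        dq = st1.q_plus - st1.q_minus
        no_u_turn = (np.dot(dq, inv_mass * st1.p_minus) >= 0) and (
            np.dot(dq, inv_mass * st1.p_plus) >= 0)
        st1.keep_going = st2.keep_going and no_u_turn and not st1.diverged
    return st1


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, rng,
               max_treedepth=_MAX_TREEDEPTH):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * np.sum(inv_mass * p0 * p0)
    log_u = h0 + np.log1p(-rng.random())  # log of u ~ Uniform(0, exp(h0))

    st = _TreeState()
    st.q_minus = st.q_plus = st.q_prop = q
    st.p_minus = st.p_plus = p0
    st.grad_minus = st.grad_plus = st.grad_prop = grad
    st.logp_prop = logp
    st.n_valid = 1
    st.keep_going = True
    st.diverged = False
    st.sum_alpha = 0.0
    st.n_alpha = 0

    depth = 0
    while st.keep_going and depth < max_treedepth:
        direction = -1 if rng.random() < 0.5 else 1
        if direction == -1:
            sub = _build_tree(logp_grad, st.q_minus, st.p_minus, st.grad_minus,
                              log_u, direction, depth, eps, inv_mass, h0, rng)
            st.q_minus, st.p_minus, st.grad_minus = sub.q_minus, sub.p_minus, sub.grad_minus
        else:
            sub = _build_tree(logp_grad, st.q_plus, st.p_plus, st.grad_plus,
                              log_u, direction, depth, eps, inv_mass, h0, rng)
            st.q_plus, st.p_plus, st.grad_plus = sub.q_plus, sub.p_plus, sub.grad_plus
        if sub.keep_going and sub.n_valid > 0:
            if rng.random() < sub.n_valid / max(st.n_valid, 1):
                st.q_prop, st.logp_prop, st.grad_prop = sub.q_prop, sub.logp_prop, sub.grad_prop
        st.n_valid += sub.n_valid
        st.sum_alpha += sub.sum_alpha
        st.n_alpha += sub.n_alpha
        st.diverged = st.diverged or sub.diverged
        dq = st.q_plus - st.q_minus
        no_u_turn = (np.dot(dq, inv_mass * st.p_minus) >= 0) and (
            np.dot(dq, inv_mass * st.p_plus) >= 0)
        st.keep_going = sub.keep_going and no_u_turn
        depth += 1

    accept_stat = st.sum_alpha / max(st.n_alpha, 1)
    return st.q_prop, st.logp_prop, st.grad_prop, accept_stat, st.diverged


def _run_chain(logp_grad, dim, warmup, draws, rng, init, target_accept,
               max_treedepth):
    q = init.copy()
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise FloatingPointError("non-finite log density at initial point")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    # Warm-up schedule: step-size-only head and tail bracket a sequence of
    # expanding mass-estimation windows (doubling lengths, Stan-style).
    head = max(1, int(0.15 * warmup))
    tail = max(1, int(0.10 * warmup))
    window_end = warmup - tail
    windows = []
    w = max(10, (window_end - head) // 15)
    pos = head
    while pos < window_end:
        w_len = min(w, window_end - pos)
        if window_end - (pos + w_len) < w:  # absorb a too-short final window
            w_len = window_end - pos
        pos += w_len
        windows.append(pos)
        w *= 2
    window_samples: list[np.ndarray] = []

    out = np.empty((draws, dim))
    divergences = 0

    for it in range(warmup + draws):
        q, logp, grad, accept_stat, diverged = _nuts_step(
            logp_grad, q, logp, grad, eps, inv_mass, rng, max_treedepth)
        if it < warmup:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= head:
                window_samples.append(q)
            if windows and it == windows[0] - 1:
                if len(window_samples) >= 10:
                    samp = np.asarray(window_samples)
                    var = samp.var(axis=0, ddof=1)
                    n_w = samp.shape[0]
                    # Shrink towards a small value as Stan regularizes.
                    inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    inv_mass = np.clip(inv_mass, 1e-10, 1e10)
                    # Re-initialize step-size adaptation for the new metric.
                    eps = _find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
                window_samples = []
                windows.pop(0)
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            out[it - warmup] = q
            if diverged:
                divergences += 1
    return out, divergences, eps, inv_mass


def nuts_sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    dim: int,
    *,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    initial_points: np.ndarray | None = None,
    target_accept: float = 0.8,
    max_treedepth: int = _MAX_TREEDEPTH,
) -> NutsResult:
    """Sample a target density with NUTS.

    Parameters
    ----------
    logp_grad
        Callable mapping an unconstrained parameter vector to
        ``(log_density, gradient)``.
    dim
        Dimension of the parameter vector.
    chains, warmup, draws
        Independent chains, warm-up iterations (discarded) and retained
        post-warm-up draws per chain.
    seed
        Seeds all chains via a :class:`numpy.random.SeedSequence` spawn, so
        identical inputs give identical output.
    initial_points
        Optional ``(chains, dim)`` array of starting points; defaults to
        jittered ``Uniform(-1, 1)`` draws per chain.
    """
    if chains < 1:
        raise ValueError("chains must be >= 1")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    all_draws = np.empty((chains, draws, dim))
    divs = np.zeros(chains, dtype=int)
    epss = np.zeros(chains)
    inv_masses = np.zeros((chains, dim))
    for c in range(chains):
        rng = np.random.default_rng(seqs[c])
        if initial_points is not None:
            init = np.asarray(initial_points[c], dtype=float)
        else:
            init = rng.uniform(-1.0, 1.0, size=dim)
        chain_draws, d, eps, im = _run_chain(
            logp_grad, dim, warmup, draws, rng, init, target_accept, max_treedepth)
        all_draws[c] = chain_draws
        divs[c] = d
        epss[c] = eps
        inv_masses[c] = im
    return NutsResult(draws=all_draws, divergences=divs, step_sizes=epss,
                      inv_mass=inv_masses)
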