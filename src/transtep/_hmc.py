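"""A compact Hamiltonian Monte Carlo sampler.

Plain HMC with leapfrog integration, dual-averaging step-size adaptation to
a target acceptance rate, jittered trajectory lengths, and a diagonal mass
matrix estimated from a warmup window.  Targets supply log density and
gradient for an unconstrained parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HMCConfig", "sample_hmc"]


@dataclass(frozen=True)
class HMCConfig:
    n_warmup: int = 400
    n_draws: int = 500
    n_chains: int = 4
    target_accept: float = 0.9
    n_leapfrog: int = 25
    jitter: float = 0.3
    init_step: float = 0.1
    seed: int = 0
    divergence_energy: float = 1000.0


def _leapfrog(logp_and_grad, q, p, step, n_steps, inv_mass):
    lp, grad = logp_and_grad(q)
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        q = q + step * inv_mass * p
        lp, grad = logp_and_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf
        p = p + (step if i < n_steps - 1 else 0.5 * step) * grad
    return q, p, lp


def _one_chain(logp_and_grad, q0, cfg: HMCConfig, rng: np.random.Generator):
    ndim = q0.size
    q = q0.copy()
    lp, _ = logp_and_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")
    inv_mass = np.ones(ndim)
    # dual averaging state
    step = cfg.init_step
    mu = np.log(10 * step)
    log_step_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    # warmup window for mass estimation
    w0, w1 = cfg.n_warmup // 4, 3 * cfg.n_warmup // 4
    window = []
    draws = np.empty((cfg.n_draws, ndim))
    divergences = 0
    accept_sum = 0.0
    total = cfg.n_warmup + cfg.n_draws
    for it in range(total):
        warming = it < cfg.n_warmup
        p = rng.normal(size=ndim) / np.sqrt(inv_mass)
        n_steps = max(1, int(cfg.n_leapfrog * (1 + cfg.jitter * (2 * rng.random() - 1))))
        lp0, _ = logp_and_grad(q)
        h0 = lp0 - 0.5 * np.dot(p * p, inv_mass)
        q_new, p_new, lp_new = _leapfrog(logp_and_grad, q, p, step, n_steps, inv_mass)
        h_new = lp_new - 0.5 * np.dot(p_new * p_new, inv_mass)
        delta = h_new - h0
        if not np.isfinite(delta) or delta < -cfg.divergence_energy:
            alpha = 0.0
            if not warming:
                divergences += 1
        else:
            alpha = min(1.0, np.exp(min(delta, 0.0)))
            if np.log(rng.random()) < delta:
                q = q_new
        if warming:
            # dual averaging toward the target acceptance rate
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (cfg.target_accept - alpha) / (m + t0)
            log_step = mu - np.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_step_bar = eta * log_step + (1 - eta) * log_step_bar
            step = np.exp(log_step)
            if w0 <= it < w1:
                window.append(q.copy())
            if it == w1 and len(window) > 10:
                var = np.var(np.asarray(window), axis=0)
                inv_mass = np.maximum(var, 1e-8)
                # re-open step adaptation around the new metric
                mu = np.log(10 * step)
                h_bar, log_step_bar = 0.0, np.log(step)
        else:
            if it == cfg.n_warmup:
                step = np.exp(log_step_bar)
            accept_sum += alpha
            draws[it - cfg.n_warmup] = q
    return draws, {
        "divergences": divergences,
        "accept_rate": accept_sum / cfg.n_draws,
        "step_size": step,
    }


def sample_hmc(logp_and_grad, init: np.ndarray, cfg: HMCConfig):
    """Run ``cfg.n_chains`` HMC chains from jittered starts.

    ``logp_and_grad(q) -> (float, ndarray)``.  Returns (draws with shape
    (n_chains, n_draws, ndim), list of per-chain info dicts).
    """
    ss = np.random.SeedSequence(cfg.seed)
    draws = []
    infos = []
    for child in ss.spawn(cfg.n_chains):
        rng = np.random.default_rng(child)
        q0 = init + 0.1 * rng.normal(size=init.size)
        d, info = _one_chain(logp_and_grad, q0, cfg, rng)
        draws.append(d)
        infos.append(info)
    return np.stack(draws), infos
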