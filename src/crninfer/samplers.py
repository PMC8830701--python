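"""Gradient-based samplers over a generic log-density with gradient.

`nuts` is a dynamic Hamiltonian Monte Carlo sampler (No-U-Turn criterion,
multinomial state selection) with dual-averaging step-size adaptation and
windowed diagonal mass-matrix estimation during warmup.  `advi` is
mean-field Gaussian variational inference on the unconstrained scale with
reparameterized stochastic gradients and Adam.

Both take `logp_grad: theta -> (float, ndarray)` and are deterministic
given the supplied Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts", "advi", "NutsStats", "AdviResult"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NutsStats:
    divergences: int = 0
    step_size: float = 0.0
    mass_diag: np.ndarray | None = None
    accept_rate: float = 0.0
    treedepths: list = field(default_factory=list)


class _Mass:
    """Euclidean metric: diagonal or dense inverse mass (posterior
    covariance estimate).  velocity(p) = M^-1 p; momentum ~ N(0, M)."""

    def __init__(self, diag=None, cov=None):
        if cov is not None:
            self.dense = True
            self.cov = cov
            self.L = np.linalg.cholesky(cov)  # cov = L L^T
        else:
            self.dense = False
            self.diag = np.maximum(diag, 1e-12)
            self._sqrt = np.sqrt(self.diag)

    def velocity(self, p):
        return self.cov @ p if self.dense else self.diag * p

    def kinetic(self, p):
        return 0.5 * float(p @ self.velocity(p))

    def sample(self, rng):
        xi = rng.standard_normal(self.L.shape[0] if self.dense
                                 else self.diag.size)
        if self.dense:
            # p ~ N(0, cov^-1): solve L^T p = xi
            from scipy.linalg import solve_triangular

            return solve_triangular(self.L.T, xi, lower=False)
        return xi / self._sqrt


def _leapfrog(logp_grad, theta, p, grad, eps, mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * mass.velocity(p)
    lp, grad = logp_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _find_initial_step(logp_grad, theta, lp, grad, mass, rng):
    eps = 1.0
    p = mass.sample(rng)
    h0 = lp - mass.kinetic(p)
    t1, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, mass)
    h1 = lp1 - mass.kinetic(p1) if np.isfinite(lp1) else -np.inf
    log_ratio = h1 - h0
    direction = 1.0 if log_ratio > math.log(0.5) else -1.0
    for _ in range(64):
        eps *= 2.0 ** direction
        t1, p1, lp1, _ = _leapfrog(logp_grad, theta, p, grad, eps, mass)
        h1 = lp1 - mass.kinetic(p1) if np.isfinite(lp1) else -np.inf
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return max(eps, 1e-10)


class _Tree:
    __slots__ = ("theta_m", "p_m", "grad_m", "theta_p", "p_p", "grad_p",
                 "theta_prop", "lp_prop", "grad_prop", "log_w", "sum_p",
                 "diverged", "turned", "sum_alpha", "n_alpha")


def _build_tree(logp_grad, theta, p, grad, depth, direction, eps, mass,
                h0, rng):
    t = _Tree()
    if depth == 0:
        theta1, p1, lp1, grad1 = _leapfrog(
            logp_grad, theta, p, grad, direction * eps, mass)
        h1 = (lp1 - mass.kinetic(p1)) if np.isfinite(lp1) else -np.inf
        dh = h1 - h0
        t.diverged = (not np.isfinite(dh)) or (dh < -_MAX_DELTA_H)
        t.turned = False
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.p_m = t.p_p = p1
        t.grad_m = t.grad_p = t.grad_prop = grad1
        t.lp_prop = lp1
        t.log_w = dh if not t.diverged else -np.inf
        t.sum_p = p1.copy()
        t.sum_alpha = min(1.0, math.exp(min(dh, 0.0))) if np.isfinite(dh) else 0.0
        t.n_alpha = 1
        return t
    # first half
    t = _build_tree(logp_grad, theta, p, grad, depth - 1, direction, eps,
                    mass, h0, rng)
    if t.diverged or t.turned:
        return t
    # second half, extending in the same direction
    if direction == 1:
        t2 = _build_tree(logp_grad, t.theta_p, t.p_p, t.grad_p, depth - 1,
                         direction, eps, mass, h0, rng)
        t.theta_p, t.p_p, t.grad_p = t2.theta_p, t2.p_p, t2.grad_p
    else:
        t2 = _build_tree(logp_grad, t.theta_m, t.p_m, t.grad_m, depth - 1,
                         direction, eps, mass, h0, rng)
        t.theta_m, t.p_m, t.grad_m = t2.theta_m, t2.p_m, t2.grad_m
    t.sum_alpha += t2.sum_alpha
    t.n_alpha += t2.n_alpha
    if t2.diverged:
        t.diverged = True
        return t
    total = np.logaddexp(t.log_w, t2.log_w)
    if np.isfinite(t2.log_w) and math.log(rng.uniform()) < t2.log_w - total:
        t.theta_prop, t.lp_prop, t.grad_prop = t2.theta_prop, t2.lp_prop, t2.grad_prop
    t.log_w = total
    t.sum_p = t.sum_p + t2.sum_p
    dtheta = t.sum_p  # momentum sum as U-turn proxy over the subtree
    t.turned = (t2.turned
                or float(dtheta @ mass.velocity(t.p_m)) <= 0
                or float(dtheta @ mass.velocity(t.p_p)) <= 0)
    return t


def _warmup_windows(n_warmup, init_buffer=75, term_buffer=50, base_window=25):
    """Stan-style schedule: step-size-only head/tail, doubling variance
    windows in between.  Returns the iteration indices ending each window."""
    if n_warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * n_warmup))
        term_buffer = max(1, int(0.1 * n_warmup))
        base_window = max(1, n_warmup - init_buffer - term_buffer)
    ends, start, w = [], init_buffer, base_window
    while start + w < n_warmup - term_buffer:
        ends.append(start + w)
        start += w
        w *= 2
    ends.append(n_warmup - term_buffer)
    return init_buffer, ends


def nuts(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    init_inv_mass: np.ndarray | None = None,
    dense_mass: bool = False,
):
    """Run one chain; returns (draws (n_draws, dim), logps, NutsStats).

    `init_inv_mass` seeds the diagonal inverse mass matrix (e.g. posterior
    variance estimates from a variational pre-fit); warmup windows refine
    it.  With `dense_mass` the windows estimate the full posterior
    covariance (shrunk toward its diagonal), which decorrelates slow
    compensating directions such as jointly-identified reaction rates.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite log density at the initial point")
    diag0 = (np.ones(dim) if init_inv_mass is None
             else np.maximum(np.asarray(init_inv_mass, dtype=float), 1e-12))
    mass = _Mass(diag=diag0)

    eps = _find_initial_step(logp_grad, theta, lp, grad, mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    da_m = 0  # dual-averaging iteration counter, reset with the mass matrix
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_buffer, window_ends = _warmup_windows(n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)
    welford_cov = np.zeros((dim, dim)) if dense_mass else None

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    stats = NutsStats()
    accepts = []

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        p = mass.sample(rng)
        h0 = lp - mass.kinetic(p)
        theta_m = theta_p = theta
        p_m = p_p = p
        grad_m = grad_p = grad
        log_w = 0.0
        sum_p = p.copy()
        sum_alpha, n_alpha = 0.0, 0
        depth, diverged = 0, False
        while depth < max_treedepth:
            direction = 1 if rng.uniform() < 0.5 else -1
            if direction == 1:
                t = _build_tree(logp_grad, theta_p, p_p, grad_p, depth, 1,
                                eps, mass, h0, rng)
                theta_p, p_p, grad_p = t.theta_p, t.p_p, t.grad_p
            else:
                t = _build_tree(logp_grad, theta_m, p_m, grad_m, depth, -1,
                                eps, mass, h0, rng)
                theta_m, p_m, grad_m = t.theta_m, t.p_m, t.grad_m
            sum_alpha += t.sum_alpha
            n_alpha += t.n_alpha
            if t.diverged:
                diverged = True
                break
            if t.turned:
                break  # subtree proposals from a turned subtree are discarded
            if np.isfinite(t.log_w) and \
                    math.log(rng.uniform()) < t.log_w - np.logaddexp(log_w, t.log_w):
                theta, lp, grad = t.theta_prop, t.lp_prop, t.grad_prop
            log_w = np.logaddexp(log_w, t.log_w)
            sum_p = sum_p + t.sum_p
            if \
                    float(sum_p @ mass.velocity(p_m)) <= 0 or \
                    float(sum_p @ mass.velocity(p_p)) <= 0:
                break
            depth += 1

        alpha = sum_alpha / max(n_alpha, 1)
        accepts.append(alpha)
        if warming:
            da_m += 1
            m = da_m
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - alpha) / (m + t0)
            log_eps = mu - math.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            # variance accumulation inside the current window
            if it >= init_buffer and it < window_ends[-1]:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
                if dense_mass:
                    welford_cov += np.outer(delta, theta - welford_mean)
                if (it + 1) in window_ends and welford_n > 1:
                    n = welford_n
                    shrink = n / (n + 5.0)
                    ridge = 1e-3 * (5.0 / (n + 5.0))
                    var = shrink * (welford_m2 / (n - 1)) + ridge
                    # short windows produce estimates worse than what they
                    # replace: keep the current metric below 50 samples,
                    # and use the dense estimate only with > dim samples
                    if n < 50:
                        pass
                    elif dense_mass and n > dim:
                        cov = shrink * (welford_cov / (n - 1))
                        np.fill_diagonal(cov, var)
                        try:
                            mass = _Mass(cov=cov)
                        except np.linalg.LinAlgError:
                            mass = _Mass(diag=var)
                    else:
                        mass = _Mass(diag=var)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    if dense_mass:
                        welford_cov[:, :] = 0.0
                    # restart dual averaging around the current step size
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar = math.log(eps), 0.0
                    da_m = 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            if diverged:
                stats.divergences += 1
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = lp
            stats.treedepths.append(depth)

    stats.step_size = eps
    inv_diag = np.diag(mass.cov) if mass.dense else mass.diag
    stats.mass_diag = 1.0 / np.maximum(inv_diag, 1e-300)
    stats.accept_rate = float(np.mean(accepts[n_warmup:])) if n_draws else 0.0
    return draws, logps, stats


@dataclass
class AdviResult:
    mean: np.ndarray
    log_sd: np.ndarray
    elbo_trace: np.ndarray

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal((n, self.mean.size))
        return self.mean + np.exp(self.log_sd) * eps


def advi(
    logp_grad,
    theta0: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    n_mc: int = 4,
    learning_rate: float = 0.05,
) -> AdviResult:
    """Mean-field Gaussian VI maximizing the ELBO with Adam.

    The entropy term is exact; the energy term uses `n_mc` reparameterized
    samples per step.  Raises if the ELBO diverges to non-finite values.
    """
    dim = np.asarray(theta0).size
    mu = np.asarray(theta0, dtype=float).copy()
    omega = np.full(dim, -2.0)  # log sd
    m = np.zeros(2 * dim)
    v = np.zeros(2 * dim)
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    elbo_trace = np.empty(n_iter)
    for it in range(n_iter):
        sd = np.exp(omega)
        g_mu = np.zeros(dim)
        g_om = np.zeros(dim)
        energy = 0.0
        for _ in range(n_mc):
            eps_s = rng.standard_normal(dim)
            theta = mu + sd * eps_s
            lp, grad = logp_grad(theta)
            if not np.isfinite(lp):
                lp, grad = -1e10, np.zeros(dim)
            energy += lp / n_mc
            g_mu += grad / n_mc
            g_om += grad * sd * eps_s / n_mc
        g_om += 1.0  # entropy gradient
        elbo = energy + float(np.sum(omega)) \
            + 0.5 * dim * (1.0 + math.log(2.0 * math.pi))
        elbo_trace[it] = elbo
        g = np.concatenate([g_mu, g_om])
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1 ** (it + 1))
        vhat = v / (1 - b2 ** (it + 1))
        step = learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        mu += step[:dim]
        omega += step[dim:]
        omega = np.clip(omega, -30.0, 10.0)
    if not np.isfinite(elbo_trace[-1]):
        raise RuntimeError("variational optimization diverged")
    return AdviResult(mu, omega, elbo_trace)
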