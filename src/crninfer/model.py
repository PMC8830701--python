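"""Joint probability model: regularized horseshoe prior over reaction rates
plus a latent-ODE (or derivative-based) observational likelihood.

Model
-----
For each free candidate reaction i (fixed/known reactions are excluded):

    lambda_i ~ Cauchy+(0, 1)
    ltilde_i^2 = c^2 lambda_i^2 / (c^2 + tau^2 lambda_i^2)
    k_i ~ Normal(0, tau * ltilde_i) truncated to k_i >= 0
    c ~ Inv-Gamma(a, b)
    sigma ~ Half-Normal(0, sigma_prior_scale)

tau is the fixed global shrinkage scale: it sets the size below which a
rate counts as absent.  The slab scale c caps how large the effective
prior scale tau*ltilde_i of a "selected" rate can grow; as c^2 -> inf the
plain horseshoe is recovered.

Latent-ODE likelihood: Z(t) solves dZ/dt = S.T (k * f(Z)) from Z(t0); an
observation map g (identity / coordinate subset / weighted sum) links Z to
observables, and measurements are median-unbiased multiplicative noise,
log X^(t_j) ~ Normal(log g(Z(t_j)), sigma^2), summed over times,
observables, and replicate trajectories.  A Poisson alternative
(X^ ~ Poisson(g(Z))) is available for integer count data.

The derivative variant regresses second-order finite-difference derivative
estimates on the mass-action basis, dX^/dt(t_j) ~ Normal(S.T (k*f(X^)), 1),
avoiding the ODE solve at the cost of derivative-estimation bias.

Sampling operates on an unconstrained vector theta with the non-centered
parameterization k_i = tau*ltilde_i * |z_i|, z_i ~ Normal(0,1), and log
transforms of (lambda, c, sigma); `HorseshoeModel.logp_and_grad` returns the
log posterior density and its exact gradient (through the discrete RK4
solution via forward sensitivities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from ._kernels import rk4_with_sensitivities
from .data import ObservationMap, TimeSeriesDataset
from .library import AnsatzLibrary

__all__ = [
    "HorseshoeConfig",
    "HorseshoeModelSpec",
    "ModelParameters",
    "HorseshoeModel",
    "regularized_scale",
    "log_prior",
    "log_likelihood_latent",
    "log_likelihood_derivative",
    "log_posterior",
    "estimate_derivatives",
]

_LOG2PI = math.log(2.0 * math.pi)
_FLOOR = 1e-10  # concentration floor applied before log inside the likelihood


@dataclass(frozen=True)
class HorseshoeConfig:
    """Prior configuration: global scale tau, Inv-Gamma(a, b) slab on c,
    and the half-normal scale of the noise prior."""

    tau: float = 1e-8
    slab_a: float = 4.0
    slab_b: float = 4.0
    sigma_prior_scale: float = 1.0

    def __post_init__(self):
        if not (self.tau > 0 and self.slab_a > 0 and self.slab_b > 0
                and self.sigma_prior_scale > 0):
            raise ValueError("tau, slab_a, slab_b, sigma_prior_scale must be > 0")


@dataclass(frozen=True)
class HorseshoeModelSpec:
    """Library + data + priors + model variant.

    fixed_reactions maps library index -> known rate; those rates are held
    constant (no prior, no sampling) but still drive the dynamics.
    """

    library: AnsatzLibrary
    datasets: tuple[TimeSeriesDataset, ...]
    config: HorseshoeConfig = field(default_factory=HorseshoeConfig)
    fixed_reactions: Mapping[int, float] = field(default_factory=dict)
    noise_model: str = "lognormal"          # "lognormal" | "poisson"
    variant: str = "latent_ode"             # "latent_ode" | "derivative"
    init_state_mode: str = "fixed_to_first_observation"  # | "inferred"
    x0: np.ndarray | None = None            # explicit initial state override
    nsub: int = 4                           # RK4 sub-steps per observation interval
    derivative_scale: float | None = 1.0    # None -> estimate the scale
    z0_prior_scale: float = 0.5             # log-scale sd of the inferred-Z0 prior
    sigma_fixed: float | None = None        # known noise scale; None -> inferred

    def __post_init__(self):
        datasets = tuple(self.datasets) if isinstance(self.datasets, (list, tuple)) \
            else (self.datasets,)
        object.__setattr__(self, "datasets", datasets)
        D = self.library.n_reactions
        fixed = {int(i): float(v) for i, v in dict(self.fixed_reactions).items()}
        for i, v in fixed.items():
            if not (0 <= i < D):
                raise ValueError(f"fixed reaction index {i} out of range")
            if v < 0:
                raise ValueError("fixed rates must be nonnegative")
        object.__setattr__(self, "fixed_reactions", fixed)
        if self.noise_model not in ("lognormal", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.variant not in ("latent_ode", "derivative"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.init_state_mode not in ("fixed_to_first_observation", "inferred"):
            raise ValueError(f"unknown init_state_mode {self.init_state_mode!r}")
        if self.x0 is not None:
            x0 = np.asarray(self.x0, dtype=float)
            if x0.shape != (self.library.n_species,):
                raise ValueError("x0 length must match the species count")
            object.__setattr__(self, "x0", x0)

    @property
    def free_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.library.n_reactions)
                     if i not in self.fixed_reactions)


@dataclass(frozen=True)
class ModelParameters:
    """Natural-scale parameters (free rates, local scales, slab, noise)."""

    k_free: np.ndarray
    lam: np.ndarray
    c: float
    sigma: float = 1.0
    z0: np.ndarray | None = None

    def __post_init__(self):
        k = np.atleast_1d(np.asarray(self.k_free, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if k.shape != lam.shape:
            raise ValueError("k_free and lam must have equal length")
        if np.any(k < 0) or np.any(lam <= 0) or self.c <= 0 or self.sigma <= 0:
            raise ValueError("positivity constraint violated")
        object.__setattr__(self, "k_free", k)
        object.__setattr__(self, "lam", lam)


def regularized_scale(lam, tau: float, c: float):
    """Effective prior scale tau * ltilde of a rate: tau*c*lam / sqrt(c^2 +
    tau^2 lam^2).  Increasing in lam, bounded above by c; ~tau*lam when
    tau*lam << c and -> c when tau*lam >> c."""
    lam = np.minimum(np.asarray(lam, dtype=float), 1e120)  # avoid overflow; limit is c
    return tau * c * lam / np.sqrt(c * c + (tau * lam) ** 2)


def estimate_derivatives(dataset: TimeSeriesDataset) -> np.ndarray:
    """Second-order finite-difference derivative estimates of the (fully
    observed) species, central in the interior and one-sided at the ends.
    Shape (L, T, N) squeezed to (T, N) for a single replicate."""
    if dataset.map.kind != "full":
        raise ValueError("derivative estimation requires complete observations")
    if dataset.n_times < 3:
        raise ValueError("need at least 3 time points for second-order stencils")
    d = np.gradient(dataset.observations, dataset.times, axis=1, edge_order=2)
    return d[0] if dataset.n_replicates == 1 else d


class HorseshoeModel:
    """Log posterior density and gradient over the unconstrained vector

        theta = [z (F), log lambda (F), log c, (log sigma), (log Z0 (N))]

    with k_i = tau*ltilde_i*|z_i|.  log sigma is present only for the
    log-normal noise model (or an estimated derivative scale); log Z0 only
    in the inferred-initial-state mode of the latent variant.
    """

    def __init__(self, spec: HorseshoeModelSpec):
        self.spec = spec
        lib = spec.library
        self.free = np.array(spec.free_indices, dtype=int)
        if self.free.size == 0:
            raise ValueError("no free reactions to infer")
        self.F = self.free.size
        self.N = lib.n_species
        self.D = lib.n_reactions
        self._Rf = lib.reactant_matrix.astype(float)
        self._Sf = lib.stoich.astype(float)
        self._k_fixed = np.zeros(self.D)
        for i, v in spec.fixed_reactions.items():
            self._k_fixed[i] = v

        self.has_sigma = (
            spec.noise_model == "lognormal" and spec.sigma_fixed is None
            if spec.variant == "latent_ode"
            else spec.derivative_scale is None
        )
        self.infer_z0 = (
            spec.variant == "latent_ode" and spec.init_state_mode == "inferred"
        )

        # parameter layout
        self.sl_z = slice(0, self.F)
        self.sl_u = slice(self.F, 2 * self.F)
        self.i_v = 2 * self.F
        n = 2 * self.F + 1
        self.i_w = n if self.has_sigma else None
        n += int(self.has_sigma)
        self.sl_q = slice(n, n + self.N) if self.infer_z0 else None
        n += self.N if self.infer_z0 else 0
        self.n_params = n

        self._prep_data()

    # -- data preparation ---------------------------------------------------

    def _x0_anchor(self, ds: TimeSeriesDataset) -> np.ndarray:
        if self.spec.x0 is not None:
            return self.spec.x0
        if ds.map.kind != "full":
            raise ValueError(
                "initial state cannot be read off a partial observation map; "
                "pass x0 explicitly or use init_state_mode='inferred' with x0"
            )
        return ds.observations[:, 0, :].mean(axis=0)

    def _prep_data(self):
        spec = self.spec
        self._ds = []
        for ds in spec.datasets:
            if ds.map.n_observables(self.N) != ds.n_observables:
                raise ValueError("observation map does not match dataset width")
            entry = {
                "times": ds.times,
                "obs": ds.observations,               # (L, T, M)
                "logobs": np.log(ds.observations),
                "mapJ": ds.map.jacobian(self.N),      # (M, N)
                "map": ds.map,
                "x0": None,
            }
            if spec.variant == "latent_ode":
                entry["x0"] = self._x0_anchor(ds) if not self.infer_z0 else None
                if self.infer_z0:
                    anchor = (spec.x0 if spec.x0 is not None
                              else self._x0_anchor(ds))
                    entry["q0"] = np.log(np.maximum(anchor, _FLOOR))
            self._ds.append(entry)
        if spec.variant == "derivative":
            if len(self._ds) != 1:
                raise ValueError("derivative variant supports a single dataset")
            ds = spec.datasets[0]
            dhat = estimate_derivatives(ds)           # (T, N)
            X = ds.values
            T = ds.n_times
            # design G[(j,n), d] = S[d,n] * f_d(X_j)
            F = np.ones((T, self.D))
            for d in range(self.D):
                for n in range(self.N):
                    m = self._Rf[d, n]
                    if m == 1.0:
                        F[:, d] *= X[:, n]
                    elif m == 2.0:
                        F[:, d] *= X[:, n] ** 2
            G = (F[:, None, :] * self._Sf.T[None, :, :]).reshape(T * self.N, self.D)
            self._deriv_G = G
            self._deriv_y = dhat.reshape(T * self.N)
        if self.infer_z0 and len(self._ds) > 1:
            raise ValueError("inferred initial state supports a single dataset")

    # -- likelihood ---------------------------------------------------------

    def _loglik_latent(self, k_full, sigma, z0_override=None):
        """Returns (loglik, dL/dk_full, dL/dsigma, dL/dz0)."""
        total = 0.0
        grad_k = np.zeros(self.D)
        grad_sigma = 0.0
        grad_z0 = np.zeros(self.N) if self.infer_z0 else None
        for entry in self._ds:
            x0 = z0_override if z0_override is not None else entry["x0"]
            traj, sk, s0, ok = rk4_with_sensitivities(
                self._Rf, self._Sf, k_full, x0, entry["times"],
                self.spec.nsub, self.infer_z0,
            )
            if not ok:
                return -np.inf, grad_k, 0.0, grad_z0
            mapJ = entry["mapJ"]                      # (M, N)
            m = entry["map"].apply(traj)              # (T, M)
            m_fl = np.maximum(m, _FLOOR)
            T, M = m.shape
            L = entry["obs"].shape[0]
            if self.spec.noise_model == "lognormal":
                logm = np.log(m_fl)
                r = entry["logobs"] - logm[None, :, :]   # (L, T, M)
                total += (
                    -0.5 * np.sum(r * r) / sigma**2
                    - L * T * M * (math.log(sigma) + 0.5 * _LOG2PI)
                    - np.sum(entry["logobs"])
                )
                grad_sigma += np.sum(r * r) / sigma**3 - L * T * M / sigma
                dL_dm = np.where(m > _FLOOR,
                                 r.sum(axis=0) / (sigma**2 * m_fl), 0.0)
            else:  # poisson
                x = entry["obs"]
                total += np.sum(x * np.log(m_fl)[None] - m_fl[None]
                                - gammaln(x + 1.0))
                dL_dm = np.where(m > _FLOOR,
                                 (x / m_fl[None] - 1.0).sum(axis=0), 0.0)
            if not np.isfinite(total):
                return -np.inf, grad_k, 0.0, grad_z0
            dL_dZ = dL_dm @ mapJ                      # (T, N)
            grad_k += np.einsum("tn,tnd->d", dL_dZ, sk)
            if self.infer_z0:
                grad_z0 += np.einsum("tn,tnm->m", dL_dZ, s0)
        return total, grad_k, grad_sigma, grad_z0

    def _loglik_derivative(self, k_full, scale):
        r = self._deriv_y - self._deriv_G @ k_full
        n = r.size
        total = (-0.5 * np.sum(r * r) / scale**2
                 - n * (math.log(scale) + 0.5 * _LOG2PI))
        grad_k = self._deriv_G.T @ r / scale**2
        grad_scale = np.sum(r * r) / scale**3 - n / scale
        return total, grad_k, grad_scale

    # -- log posterior over theta -------------------------------------------

    def logp_and_grad(self, theta: np.ndarray):
        spec, cfg = self.spec, self.spec.config
        theta = np.asarray(theta, dtype=float)
        grad = np.zeros_like(theta)
        z = theta[self.sl_z]
        u = theta[self.sl_u]
        v = theta[self.i_v]
        lam = np.exp(u)
        c = math.exp(v)
        tau = cfg.tau
        # clamp before squaring: above this the regularized scale has long
        # saturated at c and the exact value of lam no longer matters
        lam = np.minimum(lam, 1e120)
        Q = c * c + (tau * lam) ** 2
        s = tau * c * lam / np.sqrt(Q)                # tau * ltilde
        k_free = s * np.abs(z)
        k_full = self._k_fixed.copy()
        k_full[self.free] = k_free

        if self.has_sigma:
            w = theta[self.i_w]
            sigma = math.exp(w)
        else:
            sigma = (spec.derivative_scale if spec.variant == "derivative"
                     else (spec.sigma_fixed if spec.sigma_fixed is not None
                           else 1.0))

        # priors (on theta, Jacobians included)
        lp = -0.5 * float(z @ z) - 0.5 * self.F * _LOG2PI
        grad[self.sl_z] = -z
        lp += np.sum(math.log(2.0 / math.pi) - np.log1p(lam**2) + u)
        grad[self.sl_u] = -2.0 * lam**2 / (1.0 + lam**2) + 1.0
        a, b = cfg.slab_a, cfg.slab_b
        lp += a * math.log(b) - gammaln(a) - (a + 1.0) * v - b / c + v
        grad[self.i_v] = -a + b / c
        if self.has_sigma:
            ps = cfg.sigma_prior_scale
            lp += (math.log(2.0) - 0.5 * _LOG2PI - math.log(ps)
                   - 0.5 * sigma**2 / ps**2 + w)
            grad[self.i_w] = -(sigma / ps) ** 2 + 1.0

        z0 = None
        if self.infer_z0:
            q = theta[self.sl_q]
            z0 = np.exp(q)
            q0 = self._ds[0]["q0"]
            s0p = spec.z0_prior_scale
            lp += np.sum(-0.5 * ((q - q0) / s0p) ** 2
                         - 0.5 * _LOG2PI - math.log(s0p))
            grad[self.sl_q] = -(q - q0) / s0p**2

        if not np.isfinite(lp):
            return -np.inf, grad

        # likelihood
        if len(self._ds) == 0 and spec.variant == "latent_ode":
            return lp, grad
        if spec.variant == "latent_ode":
            ll, gk, gsig, gz0 = self._loglik_latent(k_full, sigma, z0)
        else:
            ll, gk, gsig = self._loglik_derivative(k_full, sigma)
            gz0 = None
        if not np.isfinite(ll):
            return -np.inf, grad

        gk_free = gk[self.free]
        # chain rule: k = s*|z|; s = s(lam, c)
        grad[self.sl_z] += gk_free * s * np.sign(z)
        dL_ds = gk_free * np.abs(z)
        # stable forms: ds/dlam * lam = s c^2 / Q, ds/dc * c = s (tau lam)^2 / Q
        grad[self.sl_u] += dL_ds * s * (c * c / Q)
        grad[self.i_v] += float(np.sum(dL_ds * s * ((tau * lam) ** 2 / Q)))
        if self.has_sigma:
            grad[self.i_w] += gsig * sigma
        if self.infer_z0:
            grad[self.sl_q] += gz0 * z0
        return lp + ll, grad

    # -- parameter conversions ----------------------------------------------

    def constrain(self, theta: np.ndarray) -> dict:
        """Natural-scale view of one unconstrained draw."""
        cfg = self.spec.config
        lam = np.exp(theta[self.sl_u])
        c = math.exp(theta[self.i_v])
        s = regularized_scale(lam, cfg.tau, c)
        k_free = s * np.abs(theta[self.sl_z])
        k_full = self._k_fixed.copy()
        k_full[self.free] = k_free
        out = {"k": k_full, "lam": lam, "c": c, "tlam": s}
        out["sigma"] = math.exp(theta[self.i_w]) if self.has_sigma else None
        out["z0"] = np.exp(theta[self.sl_q]) if self.infer_z0 else None
        return out

    def unconstrain(self, params: ModelParameters) -> np.ndarray:
        cfg = self.spec.config
        theta = np.zeros(self.n_params)
        s = regularized_scale(params.lam, cfg.tau, params.c)
        theta[self.sl_z] = params.k_free / s
        theta[self.sl_u] = np.log(params.lam)
        theta[self.i_v] = math.log(params.c)
        if self.has_sigma:
            theta[self.i_w] = math.log(params.sigma)
        if self.infer_z0:
            if params.z0 is None:
                raise ValueError("z0 required in inferred mode")
            theta[self.sl_q] = np.log(params.z0)
        return theta

    def initial_theta(self, rng: np.random.Generator, jitter: float = 2.0):
        """Uniform(-jitter, jitter) start on the unconstrained scale; chain
        dispersion is what lets different chains find different networks."""
        theta = rng.uniform(-jitter, jitter, size=self.n_params)
        if self.infer_z0:
            theta[self.sl_q] = self._ds[0]["q0"] + 0.1 * rng.standard_normal(self.N)
        return theta


# ---------------------------------------------------------------------------
# spec-level functional surface over natural parameters
# ---------------------------------------------------------------------------

def _halfnormal_logpdf(x, scale):
    return (math.log(2.0) - 0.5 * _LOG2PI - np.log(scale)
            - 0.5 * (np.asarray(x) / scale) ** 2)


def log_prior(params: ModelParameters, spec: HorseshoeModelSpec) -> float:
    """Natural-scale prior density: half-Cauchy locals, truncated-normal
    rates, Inv-Gamma slab, half-normal noise.  Fixed reactions contribute
    nothing."""
    cfg = spec.config
    lam, c = params.lam, params.c
    lp = float(np.sum(np.log(2.0 / math.pi) - np.log1p(lam**2)))
    s = regularized_scale(lam, cfg.tau, c)
    lp += float(np.sum(_halfnormal_logpdf(params.k_free, s)))
    a, b = cfg.slab_a, cfg.slab_b
    lp += a * math.log(b) - float(gammaln(a)) - (a + 1.0) * math.log(c) - b / c
    if spec.noise_model == "lognormal":
        lp += float(_halfnormal_logpdf(params.sigma, cfg.sigma_prior_scale))
    return lp


def _k_full(params: ModelParameters, spec: HorseshoeModelSpec) -> np.ndarray:
    model = HorseshoeModel(spec)
    k = model._k_fixed.copy()
    k[model.free] = params.k_free
    return k


def log_likelihood_latent(params: ModelParameters, spec: HorseshoeModelSpec) -> float:
    model = HorseshoeModel(spec)
    z0 = params.z0 if model.infer_z0 else None
    ll, *_ = model._loglik_latent(_k_full(params, spec), params.sigma, z0)
    return float(ll)


def log_likelihood_derivative(params: ModelParameters, spec: HorseshoeModelSpec) -> float:
    model = HorseshoeModel(spec)
    scale = params.sigma if model.has_sigma else spec.derivative_scale
    ll, *_ = model._loglik_derivative(_k_full(params, spec), scale)
    return float(ll)


def log_posterior(params: ModelParameters, spec: HorseshoeModelSpec) -> float:
    lp = log_prior(params, spec)
    if len(spec.datasets) == 0:
        return lp
    if spec.variant == "latent_ode":
        return lp + log_likelihood_latent(params, spec)
    return lp + log_likelihood_derivative(params, spec)
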