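"""Reactive SINDy baseline: finite-difference derivative estimates regressed
on the mass-action basis with a non-negative mixed l1/l2 penalty.

The point estimate solves

    min_k  (1/2T) sum_j || dX^/dt(t_j) - S.T (k * f(X^(t_j))) ||^2
           + alpha * lambda_mix * ||k||_1 + alpha * (1 - lambda_mix) * ||k||_2^2
    s.t.   k >= 0

via accelerated proximal gradient (FISTA) with a non-negativity projection;
with k >= 0 the l1 term is just sum(k).  A post-fit threshold converts the
continuous estimate into an active reaction set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .data import TimeSeriesDataset
from .dynamics import propensity
from .library import AnsatzLibrary
from .model import estimate_derivatives

__all__ = ["RsindyConfig", "RsindyFit", "fit_rsindy", "grid_search",
           "threshold_network", "build_regression"]

DEFAULT_ALPHA_GRID = tuple(np.logspace(-6, 1, 15))
DEFAULT_MIX_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class RsindyConfig:
    alpha: float = 1e-3
    lambda_mix: float = 1.0
    threshold: float = 1e-2
    max_iter: int = 20000
    tol: float = 1e-8  # relative objective change

    def __post_init__(self):
        if self.alpha < 0 or not (0 <= self.lambda_mix <= 1) or self.threshold < 0:
            raise ValueError("invalid rsindy configuration")


@dataclass(frozen=True)
class RsindyFit:
    k: np.ndarray
    objective: float
    active: np.ndarray          # indices with k > threshold
    config: RsindyConfig
    n_iter: int
    converged: bool


def build_regression(dataset: TimeSeriesDataset, library: AnsatzLibrary):
    """Stack (G, y) with rows (time, species): y = derivative estimates,
    G[(j,n), d] = S[d, n] * f_d(X^(t_j))."""
    if dataset.map.kind != "full":
        raise ValueError("the derivative-based baseline requires full observations")
    if dataset.n_replicates != 1:
        raise ValueError("baseline supports a single replicate")
    dhat = estimate_derivatives(dataset)
    X = dataset.values
    T, N = X.shape
    F = np.stack([propensity(library, X[j]) for j in range(T)])  # (T, D)
    G = (F[:, None, :] * library.stoich.T[None, :, :]).reshape(T * N, -1)
    return G, dhat.reshape(T * N)


def _objective(G, y, k, T, alpha, mix):
    r = G @ k - y
    return (0.5 / T * float(r @ r)
            + alpha * mix * float(np.sum(k))
            + alpha * (1 - mix) * float(k @ k))


def fit_rsindy(
    dataset: TimeSeriesDataset,
    library: AnsatzLibrary,
    config: RsindyConfig = RsindyConfig(),
) -> RsindyFit:
    """FISTA on the smooth part (data term + ridge) with the prox of the
    non-negative l1 penalty, max(0, x - step * alpha * mix)."""
    G, y = build_regression(dataset, library)
    T = dataset.n_times
    alpha, mix = config.alpha, config.lambda_mix
    GtG = G.T @ G / T
    Gty = G.T @ y / T
    # Lipschitz constant of the smooth gradient
    Lsm = float(np.linalg.eigvalsh(GtG)[-1]) + 2.0 * alpha * (1 - mix)
    step = 1.0 / max(Lsm, 1e-30)
    D = library.n_reactions
    k = np.zeros(D)
    x_prev = k.copy()
    t_prev = 1.0
    obj = _objective(G, y, k, T, alpha, mix)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        grad = GtG @ k - Gty + 2.0 * alpha * (1 - mix) * k
        x = np.maximum(0.0, k - step * (grad + 0.0)) if mix == 0 else \
            np.maximum(0.0, k - step * grad - step * alpha * mix)
        t = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev**2))
        k = x + ((t_prev - 1.0) / t) * (x - x_prev)
        k = np.maximum(k, 0.0)
        x_prev, t_prev = x, t
        if it % 20 == 0:
            new_obj = _objective(G, y, x, T, alpha, mix)
            if abs(obj - new_obj) <= config.tol * max(abs(obj), 1.0):
                obj = new_obj
                converged = True
                k = x
                break
            obj = new_obj
    else:
        k = x_prev
    if not converged and it >= config.max_iter:
        obj = _objective(G, y, k, T, alpha, mix)
    active = np.flatnonzero(k > config.threshold)
    return RsindyFit(k, _objective(G, y, k, T, alpha, mix), active, config,
                     it, converged)


def threshold_network(fit: RsindyFit, threshold: float) -> np.ndarray:
    """Indices of reactions with estimated rate above the cutoff."""
    return np.flatnonzero(fit.k > threshold)


def grid_search(
    dataset: TimeSeriesDataset,
    library: AnsatzLibrary,
    alpha_grid=DEFAULT_ALPHA_GRID,
    mix_grid=DEFAULT_MIX_GRID,
    threshold: float = 1e-2,
    selection_rule: str = "sparsest_best_fit",
) -> RsindyFit:
    """Fit every (alpha, mix) pair; select, among fits whose thresholded
    active set is of minimal size >= 1 (or the overall minimum if all are
    empty), the one with the best data term."""
    alpha_grid = tuple(alpha_grid)
    mix_grid = tuple(mix_grid)
    if not alpha_grid or not mix_grid:
        raise ValueError("grids must be nonempty")
    if selection_rule != "sparsest_best_fit":
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    G, y = build_regression(dataset, library)
    T = dataset.n_times
    fits = []
    for alpha, mix in itertools.product(alpha_grid, mix_grid):
        cfg = RsindyConfig(alpha=alpha, lambda_mix=mix, threshold=threshold)
        fit = fit_rsindy(dataset, library, cfg)
        kt = np.where(fit.k > threshold, fit.k, 0.0)
        r = G @ kt - y
        data_term = 0.5 / T * float(r @ r)
        fits.append((fit, len(fit.active), data_term))
    sizes = [s for _, s, _ in fits if s >= 1]
    target = min(sizes) if sizes else 0
    pool = [(f, s, dt) for f, s, dt in fits if s == target]
    best = min(pool, key=lambda x: x[2])
    return best[0]
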