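"""Mass-action rate functions and deterministic simulation of the
reaction-rate equations dX/dt = S.T @ (k * f(X)).

The default simulator is adaptive explicit Runge-Kutta 4(5) (scipy's RK45)
at rtol=1e-6 / atol=1e-8; a stiff fallback (LSODA) and the package's own
fixed-step RK4 (the discretization used during inference, where exact
solver/gradient consistency matters) are selectable via ``method``.
Concentrations are never clipped inside the dynamics — negative excursions
are a solver-accuracy signal and are handled by the observational model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import propensities, rhs_vec, rk4_trajectory, rk4_with_sensitivities
from .library import AnsatzLibrary

__all__ = ["Trajectory", "SimulationError", "propensity", "rhs", "simulate",
           "simulate_with_sensitivities"]


class SimulationError(RuntimeError):
    """ODE solver failure; carries the offending rate vector."""

    def __init__(self, message: str, k=None):
        super().__init__(message)
        self.k = None if k is None else np.asarray(k)


@dataclass(frozen=True)
class Trajectory:
    """Solution states on a strictly increasing time grid."""

    times: np.ndarray
    states: np.ndarray  # (#times, N)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing 1-d")
        if x.shape[0] != t.shape[0]:
            raise ValueError("states/times length mismatch")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", x)


def _check_k(library: AnsatzLibrary, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if k.shape != (library.n_reactions,):
        raise ValueError(
            f"rate vector length {k.shape} does not match library D={library.n_reactions}"
        )
    if np.any(k < 0):
        raise ValueError("rate constants must be nonnegative")
    return k


def _check_x(library: AnsatzLibrary, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape != (library.n_species,):
        raise ValueError(
            f"state length {X.shape} does not match library N={library.n_species}"
        )
    return X


def propensity(library: AnsatzLibrary, X) -> np.ndarray:
    """Mass-action rate basis f(X): f_d = prod over reactants of [conc]
    (a doubled reactant contributes the square; empty side contributes 1)."""
    X = _check_x(library, X)
    return propensities(library.reactant_matrix.astype(float), X)


def rhs(library: AnsatzLibrary, k, X) -> np.ndarray:
    """dX/dt = S.T @ (k * f(X)); exactly linear in k for fixed X."""
    k = _check_k(library, k)
    X = _check_x(library, X)
    return rhs_vec(
        library.reactant_matrix.astype(float), library.stoich.astype(float), k, X
    )


def simulate(
    library: AnsatzLibrary,
    k,
    X0,
    times,
    method: str = "RK45",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    max_steps: int = 100_000,
    nsub: int = 20,
) -> Trajectory:
    """Solve the initial-value problem and evaluate at the requested times.

    ``method`` is any scipy solver name (default adaptive RK45; "LSODA"
    for stiff systems) or "rk4" for the package's fixed-step scheme with
    ``nsub`` sub-steps per output interval.
    """
    k = _check_k(library, k)
    X0 = _check_x(library, X0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    Rf = library.reactant_matrix.astype(float)
    Sf = library.stoich.astype(float)

    if method.lower() == "rk4":
        traj, ok = rk4_trajectory(Rf, Sf, k, X0, times, nsub)
        if not ok:
            raise SimulationError("fixed-step RK4 produced non-finite states", k)
        return Trajectory(times, traj)

    def fun(t, y):
        return rhs_vec(Rf, Sf, k, y)

    if times.size == 1:
        return Trajectory(times, X0[None, :].copy())
    sol = solve_ivp(
        fun,
        (times[0], times[-1]),
        X0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"ODE solver failed: {sol.message}", k)
    return Trajectory(times, sol.y.T.copy())


def simulate_with_sensitivities(
    library: AnsatzLibrary,
    k,
    X0,
    times,
    nsub: int = 20,
    with_x0: bool = False,
):
    """Fixed-step RK4 solution plus forward sensitivities.

    Returns (Trajectory, dZ/dk of shape (T, N, D)[, dZ/dX0 of shape
    (T, N, N)]).  The sensitivities are the exact derivatives of the
    discrete RK4 solution, which is what gradient-based inference needs.
    """
    k = _check_k(library, k)
    X0 = _check_x(library, X0)
    times = np.asarray(times, dtype=float)
    Rf = library.reactant_matrix.astype(float)
    Sf = library.stoich.astype(float)
    traj, sk, s0, ok = rk4_with_sensitivities(Rf, Sf, k, X0, times, nsub, with_x0)
    if not ok:
        raise SimulationError("sensitivity integration produced non-finite states", k)
    out = (Trajectory(times, traj), sk)
    return out + (s0,) if with_x0 else out


def export_trajectory(traj: Trajectory, library: AnsatzLibrary, path) -> None:
    """CSV with a `time` column and one column per species."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=list(library.species.names))
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False)


def import_trajectory(path, library: AnsatzLibrary) -> Trajectory:
    import pandas as pd

    df = pd.read_csv(path)
    return Trajectory(df["time"].to_numpy(),
                      df[list(library.species.names)].to_numpy())
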