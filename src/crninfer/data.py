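"""Synthetic datasets, observation maps, multiplicative noise, and CSV I/O.

Two canonical fixtures are generated from printed parameters:

* Lotka-Volterra predator-prey (2 species, 3 true reactions among 16
  candidates), observed on [0, 15] at dt in {0.2, 1, 2} with
  Log-Normal(0, 0.2) multiplicative noise.
* Prokaryotic auto-regulation (5 species g, P2, gP2, r, P; 8 true
  reactions), observed on [0, 0.5] at dt = 0.05 with Log-Normal(0, 0.07)
  noise, all species starting at concentration 20.

"Log-Normal(0, sigma)" means each observation is the true value times
exp(eps), eps ~ Normal(0, sigma^2): the truth is the median of the
measurement distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import library as lib
from .dynamics import Trajectory, simulate

__all__ = [
    "ObservationMap",
    "TimeSeriesDataset",
    "SyntheticSystem",
    "apply_lognormal_noise",
    "make_lotka_volterra_dataset",
    "make_autoregulation_dataset",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class ObservationMap:
    """Links latent species to observables: all species, a subset of
    coordinates, or a single weighted sum."""

    kind: str  # "full" | "subset" | "linear_sum"
    indices: tuple[int, ...] | None = None
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("full", "subset", "linear_sum"):
            raise ValueError(f"unknown observation map kind {self.kind!r}")
        if self.kind == "subset":
            if not self.indices or len(set(self.indices)) != len(self.indices):
                raise ValueError("subset map needs distinct indices")
            object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        if self.kind == "linear_sum":
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1 or np.any(w < 0) or not np.any(w > 0):
                raise ValueError("linear_sum needs nonnegative weights, one positive")
            w.setflags(write=False)
            object.__setattr__(self, "weights", w)

    @classmethod
    def full(cls) -> "ObservationMap":
        return cls("full")

    @classmethod
    def subset(cls, indices: Sequence[int]) -> "ObservationMap":
        return cls("subset", indices=tuple(indices))

    @classmethod
    def linear_sum(cls, weights) -> "ObservationMap":
        return cls("linear_sum", weights=np.asarray(weights, dtype=float))

    def n_observables(self, n_species: int) -> int:
        if self.kind == "full":
            return n_species
        if self.kind == "subset":
            return len(self.indices)
        return 1

    def observable_names(self, species_names: Sequence[str]) -> list[str]:
        if self.kind == "full":
            return list(species_names)
        if self.kind == "subset":
            return [species_names[i] for i in self.indices]
        terms = [
            (f"{w:g}*{n}" if w != 1 else n)
            for n, w in zip(species_names, self.weights)
            if w > 0
        ]
        return ["+".join(terms)]

    def apply(self, states: np.ndarray) -> np.ndarray:
        """Map latent states (T, N) to observables (T, n_obs)."""
        states = np.asarray(states, dtype=float)
        if self.kind == "full":
            return states
        if self.kind == "subset":
            return states[..., list(self.indices)]
        return states @ self.weights[:, None]

    def jacobian(self, n_species: int) -> np.ndarray:
        """d(observable)/d(state), shape (n_obs, N)."""
        if self.kind == "full":
            return np.eye(n_species)
        if self.kind == "subset":
            J = np.zeros((len(self.indices), n_species))
            for r, i in enumerate(self.indices):
                J[r, i] = 1.0
            return J
        return self.weights[None, :].copy()


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Strictly positive observations on a sorted time grid.

    ``observations`` has shape (L, T+1, n_obs) over L replicate
    trajectories; most fixtures have L = 1.
    """

    times: np.ndarray
    observations: np.ndarray
    map: ObservationMap = field(default_factory=ObservationMap.full)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        obs = np.asarray(self.observations, dtype=float)
        if obs.ndim == 2:
            obs = obs[None, :, :]
        if obs.ndim != 3:
            raise ValueError("observations must be (T, n_obs) or (L, T, n_obs)")
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if obs.shape[1] != t.shape[0]:
            raise ValueError("observation rows do not match times")
        if np.any(obs <= 0):
            bad = np.argwhere(obs <= 0)[0]
            raise ValueError(
                f"nonpositive observation at replicate {bad[0]}, "
                f"time index {bad[1]}, observable {bad[2]} "
                "(the log-normal likelihood requires positive data)"
            )
        t.setflags(write=False)
        obs.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "observations", obs)

    @property
    def n_replicates(self) -> int:
        return self.observations.shape[0]

    @property
    def n_times(self) -> int:
        return self.times.shape[0]

    @property
    def n_observables(self) -> int:
        return self.observations.shape[2]

    @property
    def values(self) -> np.ndarray:
        """Single-replicate view, shape (T, n_obs)."""
        if self.n_replicates != 1:
            raise ValueError("dataset has multiple replicates; index observations")
        return self.observations[0]


def apply_lognormal_noise(traj: Trajectory, sigma: float, seed) -> np.ndarray:
    """Multiplicative noise: obs = state * exp(eps), eps ~ N(0, sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if np.any(traj.states <= 0):
        raise ValueError("log-normal noise requires strictly positive states")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=traj.states.shape)
    return traj.states * np.exp(eps)


@dataclass(frozen=True)
class SyntheticSystem:
    """A fixture: dataset plus everything needed to score recovery."""

    dataset: TimeSeriesDataset
    library: lib.AnsatzLibrary          # candidate library used for inference
    true_rates: np.ndarray              # length D over the candidate library
    true_indices: tuple[int, ...]       # positions of the generating reactions
    x0: np.ndarray                      # true initial state
    truth: Trajectory                   # noiseless trajectory at observation times
    sigma: float                        # noise scale used


LV_X0 = np.array([50.0, 100.0])  # (P, Y)
LV_T_END = 15.0


def make_lotka_volterra_dataset(
    dt: float = 0.2, sigma: float = 0.2, seed=0
) -> SyntheticSystem:
    """Predator-prey fixture: k=(1, 0.01, 0.3), X(t0)=(P=50, Y=100),
    observed on [0, 15] every `dt` with Log-Normal(0, sigma) noise."""
    candidates = lib.lotka_volterra_library()
    k = np.zeros(candidates.n_reactions)
    for i, v in zip(lib.LV_TRUE_INDICES, lib.LV_TRUE_RATES):
        k[i] = v
    n = int(np.floor(LV_T_END / dt + 1e-9))
    times = np.arange(n + 1) * dt
    truth = simulate(candidates, k, LV_X0, times)
    obs = apply_lognormal_noise(truth, sigma, seed)
    dataset = TimeSeriesDataset(times, obs, ObservationMap.full())
    return SyntheticSystem(
        dataset, candidates, k, lib.LV_TRUE_INDICES, LV_X0.copy(), truth, sigma
    )


AUTOREG_X0 = np.full(5, 20.0)  # (g, P2, gP2, r, P) all at 20
AUTOREG_T_END = 0.5


def make_autoregulation_dataset(
    seed=0,
    dt: float = 0.05,
    sigma: float = 0.07,
    candidate_library: lib.AnsatzLibrary | None = None,
) -> SyntheticSystem:
    """Prokaryotic auto-regulation fixture: 8-reaction truth with
    k=(0.5, 1, 0.15, 1, 0.5, 0.5, 1.5, 0.3), all species starting at 20,
    observed on [0, 0.5] at dt=0.05 with Log-Normal(0, 0.07) noise.

    By default the candidate library is the desk-scale 40-reaction preset.
    """
    candidates = candidate_library or lib.autoregulation_reduced_library()
    true_lib = lib.autoregulation_true_library()
    k_true = np.array(lib.AUTOREG_TRUE_RATES)
    n = int(np.floor(AUTOREG_T_END / dt + 1e-9))
    times = np.arange(n + 1) * dt
    truth = simulate(true_lib, k_true, AUTOREG_X0, times)
    obs = apply_lognormal_noise(truth, sigma, seed)
    dataset = TimeSeriesDataset(times, obs, ObservationMap.full())
    k = np.zeros(candidates.n_reactions)
    idx = []
    for rxn, v in zip(true_lib.reactions, k_true):
        i = candidates.index_of(rxn)
        k[i] = v
        idx.append(i)
    return SyntheticSystem(
        dataset, candidates, k, tuple(idx), AUTOREG_X0.copy(), truth, sigma
    )


# ---------------------------------------------------------------------------
# CSV I/O: `time` column, one column per observable; optional `replicate`
# column for multi-trajectory datasets.
# ---------------------------------------------------------------------------

def write_dataset(dataset: TimeSeriesDataset, path, names: Sequence[str] | None = None):
    n_obs = dataset.n_observables
    names = list(names) if names is not None else [f"obs{i}" for i in range(n_obs)]
    frames = []
    for l in range(dataset.n_replicates):
        df = pd.DataFrame(dataset.observations[l], columns=names)
        df.insert(0, "time", dataset.times)
        if dataset.n_replicates > 1:
            df.insert(0, "replicate", l)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path, map: ObservationMap | None = None) -> TimeSeriesDataset:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("dataset file needs a 'time' column")
    obs_cols = [c for c in df.columns if c not in ("time", "replicate")]
    if "replicate" in df.columns:
        reps = sorted(df["replicate"].unique())
        mats, times = [], None
        for l in reps:
            sub = df[df["replicate"] == l]
            t = sub["time"].to_numpy()
            if times is None:
                times = t
            elif t.shape != times.shape or not np.allclose(t, times):
                raise ValueError("replicates must share the time grid")
            mats.append(sub[obs_cols].to_numpy())
        if {m.shape for m in mats} != {mats[0].shape}:
            raise ValueError("ragged replicates")
        obs = np.stack(mats)
    else:
        times = df["time"].to_numpy()
        obs = df[obs_cols].to_numpy()[None, :, :]
    bad = np.argwhere(obs <= 0)
    if bad.size:
        raise ValueError(f"nonpositive value at data row {bad[0][1]} "
                         f"(replicate {bad[0][0]}, column {obs_cols[bad[0][2]]})")
    return TimeSeriesDataset(times, obs, map or ObservationMap.full())
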