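"""Network extraction: prune negligible reactions, summarize recovered
networks, posterior-predictive reconstruction, and report writing.

A free reaction i is pruned when the posterior probability that its
effective prior scale tau*ltilde_i falls below delta exceeds p0
(defaults delta=1e-3, p0=0.90).  Known (fixed) reactions are always
retained at their fixed rates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationError, simulate
from .inference import ModeGroup, PosteriorSamples, group_chains_by_mode
from .library import AnsatzLibrary, format_reaction

__all__ = ["PruneConfig", "PrunedNetwork", "prune", "posterior_predictive",
           "sensitivity_sweep", "report", "PredictiveBands"]


@dataclass(frozen=True)
class PruneConfig:
    delta: float = 1e-3
    p0: float = 0.90

    def __post_init__(self):
        if not (self.delta > 0 and 0 < self.p0 < 1):
            raise ValueError("require delta > 0 and 0 < p0 < 1")


@dataclass(frozen=True)
class PrunedNetwork:
    """Pruning outcome: retained reactions with posterior summaries."""

    retained: tuple[int, ...]            # library indices (free, kept)
    pruned: tuple[int, ...]              # library indices (free, removed)
    fixed: dict                          # index -> known rate (always kept)
    p_small: dict                        # free index -> P(tau*ltilde_i < delta)
    medians: dict                        # retained free index -> posterior median
    intervals: dict                      # retained free index -> (lo, hi) 5-95%
    config: PruneConfig

    @property
    def all_retained(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.retained) | set(self.fixed)))

    def rate_vector(self, library: AnsatzLibrary) -> np.ndarray:
        """Median-rate network: fixed rates + retained medians, zeros else."""
        k = np.zeros(library.n_reactions)
        for i, v in self.fixed.items():
            k[i] = v
        for i in self.retained:
            k[i] = self.medians[i]
        return k


def _as_samples(obj) -> PosteriorSamples:
    return obj.samples if isinstance(obj, ModeGroup) else obj


def prune(samples_or_group, config: PruneConfig = PruneConfig()) -> PrunedNetwork:
    """Apply the scale-exceedance pruning rule to pooled draws.

    On multimodal fits pass a ModeGroup: pooling chains that disagree on
    the support would average incompatible networks.
    """
    samples = _as_samples(samples_or_group)
    tl = samples.flat("tlam")           # (draws, F)
    if tl.size == 0:
        raise ValueError("samples carry no local-scale draws")
    k = samples.flat("k")
    p_small = (tl < config.delta).mean(axis=0)
    retained, pruned_idx = [], []
    p_map, medians, intervals = {}, {}, {}
    for j, i in enumerate(samples.free_indices):
        p_map[i] = float(p_small[j])
        if p_small[j] > config.p0:
            pruned_idx.append(i)
        else:
            retained.append(i)
            draws = k[:, i]
            medians[i] = float(np.median(draws))
            intervals[i] = (float(np.quantile(draws, 0.05)),
                            float(np.quantile(draws, 0.95)))
    return PrunedNetwork(
        retained=tuple(retained), pruned=tuple(pruned_idx),
        fixed=dict(samples.fixed_reactions),
        p_small=p_map, medians=medians, intervals=intervals, config=config,
    )


@dataclass(frozen=True)
class PredictiveBands:
    times: np.ndarray
    quantiles: np.ndarray     # (#quantile levels, T, N)
    levels: tuple[float, ...]
    n_used: int
    n_failed: int

    def band(self, level_lo=0.05, level_hi=0.95):
        lo = self.quantiles[self.levels.index(level_lo)]
        hi = self.quantiles[self.levels.index(level_hi)]
        return lo, hi


def posterior_predictive(
    samples_or_network,
    library: AnsatzLibrary,
    X0 = None,
    times = None,
    n_draws: int = 200,
    seed=0,
    levels=(0.05, 0.5, 0.95),
    include_noise: bool = False,
) -> PredictiveBands:
    """Simulate the ODE under sampled rate vectors; pointwise quantile bands.

    Accepts PosteriorSamples / ModeGroup (subsampled rate draws) or a
    PrunedNetwork (degenerate single median-rate simulation).  Draws whose
    simulation fails are excluded and counted.  With ``include_noise`` the
    bands describe new noisy *observations* (each trajectory is perturbed
    by its draw's log-normal measurement noise); without it they describe
    the latent trajectory only.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    sig_draws = None
    x0_draws = None
    if isinstance(samples_or_network, PrunedNetwork):
        if include_noise:
            raise ValueError("noise bands need posterior sigma draws")
        if X0 is None:
            raise ValueError("a PrunedNetwork needs an explicit X0")
        ks = samples_or_network.rate_vector(library)[None, :]
    else:
        samples = _as_samples(samples_or_network)
        k_all = samples.flat("k")
        idx = (np.arange(len(k_all)) if n_draws >= len(k_all)
               else rng.choice(len(k_all), size=n_draws, replace=False))
        ks = k_all[idx]
        if include_noise:
            if samples.sigma is None:
                raise ValueError("noise bands need posterior sigma draws")
            sig_draws = samples.flat("sigma")[idx]
        if X0 is None:
            if samples.z0 is None:
                raise ValueError("pass X0 or fit with an inferred initial state")
            x0_draws = samples.flat("z0")[idx]
    trajs, failed = [], 0
    for j, k in enumerate(ks):
        x0_j = X0 if x0_draws is None else x0_draws[j]
        try:
            states = simulate(library, k, x0_j, times, method="rk4",
                              nsub=max(4, int(np.ceil(150 / max(len(times) - 1, 1))))).states
        except SimulationError:
            failed += 1
            continue
        if sig_draws is not None:
            states = states * np.exp(
                sig_draws[j] * rng.standard_normal(states.shape))
        trajs.append(states)
    if not trajs:
        raise SimulationError("every posterior draw failed to simulate")
    stack = np.stack(trajs)
    q = np.quantile(stack, levels, axis=0)
    return PredictiveBands(times, q, tuple(levels), len(trajs), failed)


def sensitivity_sweep(samples, delta_grid, p0_grid, fit_score=None):
    """Retained-set size (and optional predictive-fit score) over a
    (delta, p0) grid.  `fit_score(PrunedNetwork) -> float` lets callers
    plug a data log-likelihood of the median retained network."""
    rows = []
    for delta in delta_grid:
        for p0 in p0_grid:
            net = prune(samples, PruneConfig(delta=delta, p0=p0))
            row = {"delta": float(delta), "p0": float(p0),
                   "n_retained": len(net.retained)}
            if fit_score is not None:
                row["fit_score"] = float(fit_score(net))
            rows.append(row)
    import pandas as pd

    return pd.DataFrame(rows)


def report(
    samples: PosteriorSamples,
    library: AnsatzLibrary,
    output_dir,
    prune_config: PruneConfig = PruneConfig(),
    X0=None,
    times=None,
    n_predictive_draws: int = 200,
    seed=0,
) -> list[ModeGroup]:
    """Write the human-readable report bundle.

    Per mode group g: `network_g.txt` (reaction strings + median rates),
    `pruning_g.csv` (reaction, P(scale<delta), median, CI), and when
    (X0, times) are given `predictive_g.csv` with 5/50/95% bands.
    `modes.json` summarizes the groups.
    """
    os.makedirs(output_dir, exist_ok=True)
    groups = group_chains_by_mode(samples, prune_config)
    modes_meta = []
    for g, group in enumerate(groups):
        net = prune(group, prune_config)
        lines = []
        if not net.all_retained:
            lines.append("(null network: every candidate reaction pruned)")
        for i in net.all_retained:
            rxn = format_reaction(library.reactions[i])
            if i in net.fixed:
                lines.append(f"{rxn}  rate={net.fixed[i]:g}  [known]")
            else:
                lo, hi = net.intervals[i]
                lines.append(f"{rxn}  rate={net.medians[i]:.4g}  "
                             f"CI90=({lo:.4g}, {hi:.4g})")
        with open(os.path.join(output_dir, f"network_{g}.txt"), "w") as fh:
            fh.write("\n".join(lines) + "\n")

        import pandas as pd

        rows = [{
            "reaction": format_reaction(library.reactions[i]),
            "index": i,
            "p_small": net.p_small[i],
            "retained": i in net.retained,
            "median": net.medians.get(i, 0.0),
            "ci05": net.intervals.get(i, (0.0, 0.0))[0],
            "ci95": net.intervals.get(i, (0.0, 0.0))[1],
        } for i in samples.free_indices]
        pd.DataFrame(rows).to_csv(
            os.path.join(output_dir, f"pruning_{g}.csv"), index=False)

        if X0 is not None and times is not None:
            bands = posterior_predictive(group, library, X0, times,
                                         n_draws=n_predictive_draws, seed=seed)
            rec = []
            for li, lev in enumerate(bands.levels):
                for ti, t in enumerate(bands.times):
                    for n, name in enumerate(library.species.names):
                        rec.append({"time": t, "observable": name,
                                    "level": lev,
                                    "value": bands.quantiles[li, ti, n]})
            pd.DataFrame(rec).to_csv(
                os.path.join(output_dir, f"predictive_{g}.csv"), index=False)

        modes_meta.append({
            "group": g,
            "chains": list(group.chains),
            "support": [format_reaction(library.reactions[i])
                        for i in net.all_retained],
            "mean_logp": group.mean_logp,
        })
    with open(os.path.join(output_dir, "modes.json"), "w") as fh:
        json.dump(modes_meta, fh, indent=1)
    return groups
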