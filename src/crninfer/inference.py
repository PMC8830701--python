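"""Posterior computation: MCMC (No-U-Turn) and variational approximation,
chain management, diagnostics, and grouping of chains by discovered network.

Chain initialization
--------------------
The posterior over local scales spans many orders of magnitude (the global
scale tau is deliberately tiny), so a cold start in the fully-shrunken
region mixes impractically slowly.  Each chain therefore starts from a
cheap non-negative least-squares fit of the derivative-based regression
(when the data are fully observed): the unconstrained coordinates are
jittered Uniform(-2, 2) and the local log-scales are lifted so the implied
rates match the point estimate.  A short mean-field variational pre-fit
then supplies the starting point and the initial diagonal mass matrix for
the No-U-Turn sampler.  Chains remain free to — and on multimodal problems
do — settle into different sparse networks; diagnostics and pruning are
therefore computed per mode group, never pooled across disagreeing chains.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .model import HorseshoeModel, HorseshoeModelSpec, regularized_scale
from .samplers import advi, nuts

__all__ = ["PosteriorSamples", "ModeGroup", "run_mcmc", "run_vi",
           "group_chains_by_mode", "save_samples", "load_samples",
           "split_rhat"]


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws on the natural scale, with diagnostics.

    Arrays are indexed (chain, draw, ...).  `tlam` holds the effective
    per-reaction prior scales tau*ltilde_i used by the pruning rule.
    """

    k: np.ndarray                   # (C, S, D) full rate vectors
    lam: np.ndarray                 # (C, S, F)
    tlam: np.ndarray                # (C, S, F)
    c: np.ndarray                   # (C, S)
    sigma: np.ndarray | None        # (C, S) or None
    z0: np.ndarray | None           # (C, S, N) or None
    logp: np.ndarray                # (C, S)
    free_indices: tuple[int, ...]
    fixed_reactions: dict
    spec: HorseshoeModelSpec
    divergences: tuple[int, ...]
    seed: int
    method: str
    config_digest: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.k.shape[0]

    @property
    def n_draws(self) -> int:
        return self.k.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def select_chains(self, chains) -> "PosteriorSamples":
        idx = list(chains)
        return PosteriorSamples(
            k=self.k[idx], lam=self.lam[idx], tlam=self.tlam[idx],
            c=self.c[idx],
            sigma=None if self.sigma is None else self.sigma[idx],
            z0=None if self.z0 is None else self.z0[idx],
            logp=self.logp[idx],
            free_indices=self.free_indices,
            fixed_reactions=self.fixed_reactions,
            spec=self.spec,
            divergences=tuple(self.divergences[i] for i in idx),
            seed=self.seed, method=self.method,
            config_digest=self.config_digest,
            diagnostics=self.diagnostics,
        )


@dataclass
class ModeGroup:
    """Chains whose pruned networks share the same support set."""

    chains: tuple[int, ...]
    support: tuple[int, ...]        # retained free-reaction indices
    samples: PosteriorSamples       # restricted to the member chains
    mean_logp: float


def _config_digest(spec: HorseshoeModelSpec) -> str:
    payload = {
        "reactions": [str(r) for r in spec.library.reactions],
        "tau": spec.config.tau,
        "slab": [spec.config.slab_a, spec.config.slab_b],
        "sigma_prior": spec.config.sigma_prior_scale,
        "fixed": sorted(spec.fixed_reactions.items()),
        "noise": spec.noise_model,
        "variant": spec.variant,
        "init_state": spec.init_state_mode,
        "n_datasets": len(spec.datasets),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _warm_rate_estimate(spec: HorseshoeModelSpec) -> np.ndarray | None:
    """Non-negative least squares on the finite-difference regression;
    None when the data are not fully observed (cold start instead)."""
    from .rsindy import build_regression

    try:
        ds = spec.datasets[0]
        G, y = build_regression(ds, spec.library)
    except (ValueError, IndexError):
        return None
    fixed = spec.fixed_reactions
    if fixed:
        k_fix = np.zeros(spec.library.n_reactions)
        for i, v in fixed.items():
            k_fix[i] = v
        y = y - G @ k_fix
    free = list(spec.free_indices)
    khat_free, _ = nnls(G[:, free], y)
    khat = np.zeros(spec.library.n_reactions)
    khat[free] = khat_free
    return khat


def _initial_theta(model: HorseshoeModel, rng, khat, jitter: float = 2.0):
    theta = model.initial_theta(rng, jitter=jitter)
    if khat is not None:
        z = theta[model.sl_z]
        tau = model.spec.config.tau
        lifted = khat[model.free] / np.maximum(tau * np.abs(z), 1e-300)
        theta[model.sl_u] = np.log(np.maximum(lifted, np.exp(theta[model.sl_u])))
    return theta


def _collect(model, draws_theta, logps, spec):
    S = draws_theta.shape[0]
    D, F, N = model.D, model.F, model.N
    k = np.empty((S, D))
    lam = np.empty((S, F))
    tlam = np.empty((S, F))
    c = np.empty(S)
    sigma = np.empty(S) if model.has_sigma else None
    z0 = np.empty((S, N)) if model.infer_z0 else None
    for s in range(S):
        p = model.constrain(draws_theta[s])
        k[s] = p["k"]
        lam[s] = p["lam"]
        tlam[s] = p["tlam"]
        c[s] = p["c"]
        if sigma is not None:
            sigma[s] = p["sigma"]
        if z0 is not None:
            z0[s] = p["z0"]
    return k, lam, tlam, c, sigma, z0


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat: each chain is halved before the between/within
    comparison, so a single poorly-mixing chain is still flagged."""
    import warnings

    import arviz as az

    C, S = x.shape
    half = S // 2
    split = x[:, : 2 * half].reshape(2 * C, half)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(split))


def _diagnostics(k_chains: np.ndarray, free) -> dict:
    """Split-R-hat and bulk ESS per free rate (pooled across all chains;
    interpret per ModeGroup on multimodal problems)."""
    import warnings

    import arviz as az

    out = {"rhat": {}, "ess": {}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, i in enumerate(free):
            x = k_chains[:, :, i]
            out["rhat"][int(i)] = split_rhat(x)
            out["ess"][int(i)] = float(az.ess(x))
    return out


def run_mcmc(
    spec: HorseshoeModelSpec,
    chains: int = 4,
    warmup: int = 500,
    draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.85,
    max_treedepth: int = 8,
    jitter: float = 2.0,
    warm_start: bool = True,
    vi_init_iters: int = 1200,
    max_init_retries: int = 3,
    dense_mass: bool = False,
    progress: bool = False,
) -> PosteriorSamples:
    """Draw posterior samples with the No-U-Turn sampler.

    Reproducible for a given (seed, spec); chain c uses an independent
    stream spawned from the seed.  Divergent transitions are counted per
    chain; a chain whose every transition diverges raises.
    """
    model = HorseshoeModel(spec)
    khat = _warm_rate_estimate(spec) if warm_start else None
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    all_theta, all_logp, divs = [], [], []
    for ci in range(chains):
        rng = np.random.default_rng(chain_seeds[ci])
        last_err = None
        for attempt in range(max_init_retries):
            theta0 = _initial_theta(model, rng, khat, jitter)
            try:
                pre = advi(model.logp_and_grad, theta0, vi_init_iters, rng,
                           n_mc=2, learning_rate=0.03)
                inv_mass = np.exp(2.0 * pre.log_sd)
                d, lps, st = nuts(
                    model.logp_and_grad, pre.mean.copy(), warmup, draws, rng,
                    target_accept=target_accept, max_treedepth=max_treedepth,
                    init_inv_mass=inv_mass, dense_mass=dense_mass,
                )
                break
            except RuntimeError as err:
                last_err = err
        else:
            raise RuntimeError(
                f"chain {ci} failed to initialize after "
                f"{max_init_retries} attempts: {last_err}"
            )
        if st.divergences >= draws:
            raise RuntimeError(f"chain {ci}: every transition diverged")
        if progress:
            print(f"chain {ci}: {st.divergences} divergences, "
                  f"accept {st.accept_rate:.2f}, step {st.step_size:.3g}")
        all_theta.append(d)
        all_logp.append(lps)
        divs.append(st.divergences)

    C = chains
    parts = [_collect(model, all_theta[c], all_logp[c], spec) for c in range(C)]
    k = np.stack([p[0] for p in parts])
    samples = PosteriorSamples(
        k=k,
        lam=np.stack([p[1] for p in parts]),
        tlam=np.stack([p[2] for p in parts]),
        c=np.stack([p[3] for p in parts]),
        sigma=None if parts[0][4] is None else np.stack([p[4] for p in parts]),
        z0=None if parts[0][5] is None else np.stack([p[5] for p in parts]),
        logp=np.stack(all_logp),
        free_indices=tuple(int(i) for i in model.free),
        fixed_reactions=dict(spec.fixed_reactions),
        spec=spec,
        divergences=tuple(divs),
        seed=seed,
        method="nuts",
        config_digest=_config_digest(spec),
    )
    samples.diagnostics = _diagnostics(k, samples.free_indices)
    return samples


def run_vi(
    spec: HorseshoeModelSpec,
    iterations: int = 4000,
    seed: int = 0,
    draws: int = 1000,
    warm_start: bool = True,
    jitter: float = 2.0,
) -> PosteriorSamples:
    """Mean-field variational approximation; draws are resampled from the
    fitted Gaussian on the unconstrained scale (one pseudo-chain)."""
    model = HorseshoeModel(spec)
    khat = _warm_rate_estimate(spec) if warm_start else None
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta0 = _initial_theta(model, rng, khat, jitter)
    res = advi(model.logp_and_grad, theta0, iterations, rng, n_mc=2,
               learning_rate=0.03)
    thetas = res.sample(draws, rng)
    logps = np.array([model.logp_and_grad(t)[0] for t in thetas])
    k, lam, tlam, c, sigma, z0 = _collect(model, thetas, logps, spec)
    return PosteriorSamples(
        k=k[None], lam=lam[None], tlam=tlam[None], c=c[None],
        sigma=None if sigma is None else sigma[None],
        z0=None if z0 is None else z0[None],
        logp=logps[None],
        free_indices=tuple(int(i) for i in model.free),
        fixed_reactions=dict(spec.fixed_reactions),
        spec=spec,
        divergences=(0,),
        seed=seed,
        method="advi",
        config_digest=_config_digest(spec),
    )


def _chain_support(samples: PosteriorSamples, chain: int, delta, p0):
    tl = samples.tlam[chain]
    p_small = (tl < delta).mean(axis=0)
    return tuple(
        int(samples.free_indices[j]) for j in range(tl.shape[1])
        if p_small[j] <= p0
    )


def group_chains_by_mode(samples: PosteriorSamples, prune_config) -> list[ModeGroup]:
    """Partition chains by the support set their own draws imply under the
    pruning rule; order groups by mean within-group log posterior."""
    groups: dict[tuple, list[int]] = {}
    for ci in range(samples.n_chains):
        sup = _chain_support(samples, ci, prune_config.delta, prune_config.p0)
        groups.setdefault(sup, []).append(ci)
    out = []
    for sup, members in groups.items():
        sub = samples.select_chains(members)
        out.append(ModeGroup(
            chains=tuple(members), support=sup, samples=sub,
            mean_logp=float(sub.logp.mean()),
        ))
    out.sort(key=lambda g: -g.mean_logp)
    return out


# ---------------------------------------------------------------------------
# posterior archive: tabular draws + JSON sidecar
# ---------------------------------------------------------------------------

def save_samples(samples: PosteriorSamples, prefix) -> None:
    """Write `<prefix>.csv` (one row per draw) and `<prefix>.json`."""
    import pandas as pd

    C, S, D = samples.k.shape
    F = len(samples.free_indices)
    cols = {}
    cols["chain"] = np.repeat(np.arange(C), S)
    cols["iteration"] = np.tile(np.arange(S), C)
    for d in range(D):
        cols[f"k[{d}]"] = samples.flat("k")[:, d]
    for j, i in enumerate(samples.free_indices):
        cols[f"lam[{i}]"] = samples.flat("lam")[:, j]
        cols[f"tlam[{i}]"] = samples.flat("tlam")[:, j]
    cols["c"] = samples.flat("c")
    if samples.sigma is not None:
        cols["sigma"] = samples.flat("sigma")
    if samples.z0 is not None:
        for n in range(samples.z0.shape[2]):
            cols[f"z0[{n}]"] = samples.flat("z0")[:, n]
    cols["logp"] = samples.flat("logp")
    pd.DataFrame(cols).to_csv(f"{prefix}.csv", index=False)
    side = {
        "free_indices": list(samples.free_indices),
        "fixed_reactions": {str(k): v for k, v in samples.fixed_reactions.items()},
        "divergences": list(samples.divergences),
        "seed": samples.seed,
        "method": samples.method,
        "config_digest": samples.config_digest,
        "diagnostics": samples.diagnostics,
        "reactions": [str(r) for r in samples.spec.library.reactions],
        "species": list(samples.spec.library.species.names),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_samples(prefix, spec: HorseshoeModelSpec) -> PosteriorSamples:
    import pandas as pd

    df = pd.read_csv(f"{prefix}.csv")
    with open(f"{prefix}.json") as fh:
        side = json.load(fh)
    C = df["chain"].nunique()
    S = df["iteration"].nunique()
    free = [int(i) for i in side["free_indices"]]
    D = spec.library.n_reactions

    def grab(names):
        return df[names].to_numpy().reshape(C, S, len(names))

    k = grab([f"k[{d}]" for d in range(D)])
    lam = grab([f"lam[{i}]" for i in free])
    tlam = grab([f"tlam[{i}]" for i in free])
    sigma = grab(["sigma"])[:, :, 0] if "sigma" in df.columns else None
    z0cols = [c for c in df.columns if c.startswith("z0[")]
    z0 = grab(z0cols) if z0cols else None
    return PosteriorSamples(
        k=k, lam=lam, tlam=tlam, c=grab(["c"])[:, :, 0], sigma=sigma, z0=z0,
        logp=grab(["logp"])[:, :, 0],
        free_indices=tuple(free),
        fixed_reactions={int(i): v for i, v in side["fixed_reactions"].items()},
        spec=spec,
        divergences=tuple(side["divergences"]),
        seed=side["seed"], method=side["method"],
        config_digest=side["config_digest"],
        diagnostics=side["diagnostics"],
    )
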