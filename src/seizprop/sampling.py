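"""MCMC sampling of the seizure models and convergence diagnostics.

``sample_single`` targets the excitabilities of one seizure with the
hyperparameters fixed; ``sample_multi`` targets the hierarchical model
jointly over (q, {c_k}).  The default backend is the package's gradient-based
No-U-Turn sampler (exact piecewise gradients of the event-driven forward
map); ``method="ensemble"`` switches to the affine-invariant ensemble
sampler (emcee), a gradient-free fallback practical for small networks.

Diagnostics follow the usual practice: split-chain R-hat and effective
sample size (via arviz), plus a stuck-chain flag raised when a chain's
within-chain log-posterior variance is essentially zero.  Seizure fits in
which every chain is stuck must be excluded from downstream analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nuts import nuts_chain
from .connectome import Connectome
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .observations import MultiSeizureData, SeizureObservation
from .posterior import MultiSeizureTarget, SingleSeizureTarget

__all__ = [
    "PosteriorSamples",
    "sample_single",
    "sample_multi",
    "diagnostics",
    "q_point_estimate",
]

STUCK_VARIANCE_THRESHOLD = 1e-8


@dataclass
class PosteriorSamples:
    """Per-chain posterior draws (constrained scale) with sampler statistics."""

    draws: np.ndarray          # (n_chains, n_draws, dim)
    param_names: list[str]
    logp: np.ndarray           # (n_chains, n_draws)
    stats: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """All draws pooled over chains: (n_chains * n_draws, dim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def get(self, name: str) -> np.ndarray:
        """Pooled draws of one named parameter."""
        return self.flat()[:, self.param_names.index(name)]

    def stuck_chains(self, threshold: float = STUCK_VARIANCE_THRESHOLD) -> np.ndarray:
        """A chain is stuck when its log-posterior barely moves."""
        return self.logp.var(axis=1) < threshold

    def all_stuck(self) -> bool:
        return bool(self.stuck_chains().all())

    # -- I/O: long-format CSV + JSON diagnostics summary
    def to_csv(self, path: str | Path) -> None:
        ch, dr, dim = self.draws.shape
        chain_col = np.repeat(np.arange(ch), dr * dim)
        draw_col = np.tile(np.repeat(np.arange(dr), dim), ch)
        name_col = np.tile(np.asarray(self.param_names, dtype=object), ch * dr)
        pd.DataFrame(
            {
                "chain": chain_col,
                "draw": draw_col,
                "parameter": name_col,
                "value": self.draws.ravel(),
            }
        ).to_csv(path, index=False)

    def diagnostics_to_json(self, path: str | Path) -> None:
        rhat, ess, stuck = diagnostics(self)
        Path(path).write_text(
            json.dumps(
                {
                    "rhat": dict(zip(self.param_names, np.asarray(rhat, dtype=float).tolist())),
                    "n_eff": dict(zip(self.param_names, np.asarray(ess, dtype=float).tolist())),
                    "stuck_chains": np.asarray(stuck, dtype=bool).tolist(),
                },
                indent=2,
            )
        )


def diagnostics(samples: PosteriorSamples, stuck_threshold: float = STUCK_VARIANCE_THRESHOLD):
    """Split-chain R-hat and effective sample size per parameter, plus
    per-chain stuck flags.  Requires at least two chains."""
    if samples.n_chains < 2:
        raise ValueError("convergence diagnostics require at least two chains")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(samples.draws)
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    # classical definition caps N_eff at the total number of draws
    ess = np.minimum(ess, samples.n_chains * samples.n_draws)
    return rhat, ess, samples.stuck_chains(stuck_threshold)


def _run_chains(target, *, chains, warmup, draws, seed, method, nuts_kwargs):
    rng_root = np.random.SeedSequence(seed)
    if method == "nuts":
        chain_draws, chain_logp = [], []
        divs, step_sizes = [], []
        for ss in rng_root.spawn(chains):
            rng = np.random.default_rng(ss)
            x0 = target.initial_position(rng)
            res = nuts_chain(
                target, x0, n_warmup=warmup, n_draws=draws,
                seed=rng, **nuts_kwargs,
            )
            con = np.apply_along_axis(target.constrain, 1, res.draws)
            chain_draws.append(con)
            chain_logp.append(res.logp)
            divs.append(res.divergences)
            step_sizes.append(res.step_size)
        stats = {"method": "nuts", "divergences": divs, "step_size": step_sizes, "seed": seed}
        ps = PosteriorSamples(
            np.stack(chain_draws), list(target.param_names), np.stack(chain_logp), stats
        )
        total_div = sum(divs)
        if total_div > 0.1 * chains * draws:
            warnings.warn(
                f"divergence-dominated run: {total_div} divergent transitions "
                f"out of {chains * draws} draws",
                RuntimeWarning,
            )
        return ps
    if method == "ensemble":
        import emcee

        rng = np.random.default_rng(rng_root)
        dim = target.dim
        nwalkers = max(2 * dim + 2, 2 * chains)
        nwalkers += nwalkers % 2
        p0 = np.stack([target.initial_position(rng) for _ in range(nwalkers)])
        sampler = emcee.EnsembleSampler(nwalkers, dim, target.logp)
        state = sampler.run_mcmc(
            p0, warmup + draws, progress=False, skip_initial_state_check=True
        )
        del state
        chain = sampler.get_chain(discard=warmup)            # (draws, walkers, dim)
        lp = sampler.get_log_prob(discard=warmup).T          # (walkers, draws)
        con = np.apply_along_axis(target.constrain, 2, np.moveaxis(chain, 0, 1))
        return PosteriorSamples(
            con,
            list(target.param_names),
            lp,
            {"method": "ensemble", "n_walkers": nwalkers, "seed": seed},
        )
    raise ValueError(f"unknown sampling method {method!r}")


def sample_single(
    obs: SeizureObservation,
    W: Connectome,
    q,
    *,
    chains: int = 2,
    warmup: int = 500,
    draws: int = 500,
    seed,
    method: str = "nuts",
    constants: ModelConstants = DEFAULT_CONSTANTS,
    **nuts_kwargs,
) -> PosteriorSamples:
    """Sample the excitabilities c of one seizure with q fixed.

    Chains start from independent prior draws of c; the run is deterministic
    given ``seed`` and the backend.
    """
    target = SingleSeizureTarget(obs, W, q, constants)
    return _run_chains(
        target, chains=chains, warmup=warmup, draws=draws, seed=seed,
        method=method, nuts_kwargs=nuts_kwargs,
    )


def sample_multi(
    data: MultiSeizureData,
    *,
    chains: int = 4,
    warmup: int = 500,
    draws: int = 500,
    seed,
    method: str = "nuts",
    constants: ModelConstants = DEFAULT_CONSTANTS,
    **nuts_kwargs,
) -> PosteriorSamples:
    """Sample (q, {c_k}) of the hierarchical multi-seizure model.

    Draws are reported on the constrained scale; the first four parameters
    are q_aa, q_ab, q_ba_star, q_bb_star.  The conventional point estimate
    of the hyperparameters is the posterior mean of each component
    (``q_point_estimate``).
    """
    target = MultiSeizureTarget(data, constants)
    ps = _run_chains(
        target, chains=chains, warmup=warmup, draws=draws, seed=seed,
        method=method, nuts_kwargs=nuts_kwargs,
    )
    ps.stats["q_names"] = ["q_aa", "q_ab", "q_ba_star", "q_bb_star"]
    return ps


def q_point_estimate(samples: PosteriorSamples):
    """Posterior-mean point estimate of the hyperparameters q."""
    from .dynamics import ExcitationParams

    q = samples.flat()[:, :4].mean(axis=0)
    return ExcitationParams.from_array(q)
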