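"""Metropolis-Hastings sampling of the Boltzmann target on sequence space.

Chains start at the wild type and propose uniform single substitutions
within the d_lim Hamming ball. Because the legal neighborhood shrinks at the
ball boundary, the plain Metropolis ratio is not exactly balanced there; the
sampler applies the Hastings correction |N(x)| / |N(x')| by default, with a
plain-ratio mode retained for replication of the original recipe. Burn-in is
chosen with the Gelman-Rubin potential-scale-reduction statistic computed on
the per-chain log unnormalized density, scanning candidate cut points and
taking the earliest one that brings the statistic under threshold; if none
does, the driver extends every chain and retries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ebm import EnergyModel
from .seqspace import SearchConstraints, VariantSequence, WildType, neighborhood_size, random_neighbor


@dataclass
class ChainState:
    """One MCMC chain: current state plus the full per-step trace."""

    current: VariantSequence
    step: int = 0
    sequences: list[str] = field(default_factory=list)
    log_densities: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 8
    n_steps: int = 20_000
    d_lim: int = 6
    gr_threshold: float = 1.1
    extension_steps: int = 20_000
    max_extensions: int = 3
    seed: int = 0
    hastings_correction: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_steps, self.extension_steps) <= 0:
            raise ValueError("chain counts and step counts must be positive")
        if self.d_lim < 0 or self.gr_threshold <= 0:
            raise ValueError("d_lim and gr_threshold must be positive")


def mh_step(
    state: ChainState,
    target: EnergyModel,
    wt: WildType,
    constraints: SearchConstraints,
    rng: np.random.Generator,
    hastings_correction: bool = True,
) -> ChainState:
    """One proposal/accept-reject step; rejections repeat the current state."""
    x = state.current
    proposal = random_neighbor(x, wt, constraints, rng)
    log_ratio = target.log_unnorm_density(proposal.sequence) - target.log_unnorm_density(
        x.sequence
    )
    if hastings_correction:
        log_ratio += np.log(neighborhood_size(x.sequence, wt, constraints)) - np.log(
            neighborhood_size(proposal.sequence, wt, constraints)
        )
    accept = log_ratio >= 0 or rng.random() < np.exp(log_ratio)
    nxt = proposal if accept else x
    state.current = nxt
    state.step += 1
    state.sequences.append(nxt.sequence)
    state.log_densities.append(target.log_unnorm_density(nxt.sequence))
    state.accepted.append(bool(accept))
    return state


def run_chains(
    cfg: MCMCConfig,
    target: EnergyModel,
    wt: WildType,
    constraints: SearchConstraints | None = None,
) -> list[ChainState]:
    """Run ``n_chains`` independent chains from the wild type.

    Per-chain RNGs are spawned from the master seed via
    ``numpy.random.SeedSequence`` so traces are reproducible and chains get
    disjoint streams.
    """
    constraints = constraints or SearchConstraints(d_lim=cfg.d_lim)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [
        ChainState(current=VariantSequence.from_wildtype(wt.sequence, wt))
        for _ in range(cfg.n_chains)
    ]
    for chain, ss in zip(chains, streams):
        rng = np.random.default_rng(ss)
        for _ in range(cfg.n_steps):
            mh_step(chain, target, wt, constraints, rng, cfg.hastings_correction)
    return chains


def extend_chains(
    chains: list[ChainState],
    cfg: MCMCConfig,
    target: EnergyModel,
    wt: WildType,
    constraints: SearchConstraints | None = None,
    extension_index: int = 1,
) -> list[ChainState]:
    """Continue existing chains for ``extension_steps`` more steps."""
    constraints = constraints or SearchConstraints(d_lim=cfg.d_lim)
    streams = np.random.SeedSequence((cfg.seed, extension_index)).spawn(len(chains))
    for chain, ss in zip(chains, streams):
        rng = np.random.default_rng(ss)
        for _ in range(cfg.extension_steps):
            mh_step(chain, target, wt, constraints, rng, cfg.hastings_correction)
    return chains


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor on a per-chain scalar series.

    ``traces`` is (n_chains, n_steps). All-constant identical chains are the
    degenerate converged case and return exactly 1.0.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 2:
        raise ValueError("need >= 2 chains of length >= 2")
    m, n = traces.shape
    chain_means = traces.mean(axis=1)
    W = float(np.mean(traces.var(axis=1, ddof=1)))
    B = n * float(np.var(chain_means, ddof=1))
    if W == 0.0:
        import warnings

        warnings.warn("degenerate traces: zero within-chain variance", RuntimeWarning)
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def select_burnin(
    chains: list[ChainState], cfg: MCMCConfig, grid_fraction: float = 0.05
) -> tuple[int, bool]:
    """Earliest burn-in cut ``b`` with a converged post-``b`` Gelman-Rubin.

    Scans cut points every ``grid_fraction`` of the trace length and returns
    the smallest one at which the statistic on the retained log densities is
    below threshold; ``converged=False`` signals the driver to extend.
    """
    n = min(len(c.log_densities) for c in chains)
    traces = np.array([c.log_densities[:n] for c in chains])
    step = max(1, int(round(grid_fraction * n)))
    for b in range(0, n - 1, step):
        if n - b < 2:
            break
        if gelman_rubin(traces[:, b:]) < cfg.gr_threshold:
            return b, True
    return n, False


def sample_posterior_sequences(
    cfg: MCMCConfig,
    target: EnergyModel,
    wt: WildType,
    constraints: SearchConstraints | None = None,
) -> tuple[list[str], dict]:
    """Full driver: run chains, pick burn-in, extend until converged.

    Returns the pooled post-burn-in visited sequences (with multiplicity)
    and a convergence report.
    """
    constraints = constraints or SearchConstraints(d_lim=cfg.d_lim)
    chains = run_chains(cfg, target, wt, constraints)
    burnin, ok = select_burnin(chains, cfg)
    extensions = 0
    while not ok and extensions < cfg.max_extensions:
        extensions += 1
        chains = extend_chains(chains, cfg, target, wt, constraints, extensions)
        burnin, ok = select_burnin(chains, cfg)
    n = min(len(c.log_densities) for c in chains)
    if not ok:
        burnin = n // 2  # non-converged fallback: discard the first half
    pooled = [s for c in chains for s in c.sequences[burnin:]]
    report = {
        "burnin": int(burnin),
        "converged": bool(ok),
        "extensions": extensions,
        "total_steps": int(n),
        "gelman_rubin": float(
            gelman_rubin(np.array([c.log_densities[:n] for c in chains])[:, burnin:])
        )
        if burnin < n - 2
        else float("nan"),
        "acceptance_rate": float(np.mean([np.mean(c.accepted) for c in chains])),
    }
    return pooled, report
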