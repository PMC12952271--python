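"""Energy function, linear scalarization, and the Boltzmann log-density.

The target distribution is p(x) proportional to p_HUM(x) * exp(-E(x)/T) with
E(x) = sum_i w_i f_i(x), sum w_i = 1, where the f_i are the negated
objectives (lower energy = better). The canonical two-property
instantiation is E(x) = -w * f_aff(x; beta) - (1-w) * f_sol(x). The
normalization Z is never computed: samplers only ever use density ratios.

Property evaluations are memoized by sequence — the GP posterior is the
expensive term and MCMC revisits states constantly. The user-facing
temperature knob is the inverse temperature T^-1 (typical settings 10-30).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .humanness import AutoregressivePrior, UniformPrior

PropertyFn = Callable[[str], float]


@dataclass
class EnergyModel:
    """Scalarized energy plus humanness prior defining the Boltzmann target.

    ``properties`` are (name, fn) pairs whose fn values are already negated
    objectives; ``weights`` must be non-negative and sum to 1.
    """

    properties: Sequence[tuple[str, PropertyFn]]
    weights: Sequence[float]
    inv_temperature: float = 10.0
    prior: AutoregressivePrior = field(default_factory=UniformPrior)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.properties):
            raise ValueError("one weight per property required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if self.inv_temperature <= 0:
            raise ValueError("inverse temperature must be positive")
        self.weights = w
        self._energy_cache: dict[str, float] = {}
        self._prior_cache: dict[str, float] = {}

    @classmethod
    def from_objectives(
        cls,
        objectives: Sequence[tuple[str, PropertyFn]],
        weights: Sequence[float],
        inv_temperature: float = 10.0,
        prior: AutoregressivePrior | None = None,
    ) -> "EnergyModel":
        """Build from to-be-maximized objectives; negation applied here."""
        props = [(name, (lambda f: lambda s: -f(s))(fn)) for name, fn in objectives]
        return cls(
            properties=props,
            weights=weights,
            inv_temperature=inv_temperature,
            prior=prior if prior is not None else UniformPrior(),
        )

    @property
    def temperature(self) -> float:
        return 1.0 / self.inv_temperature

    def energy(self, seq: str) -> float:
        """E(x) = sum_i w_i f_i(x); failures carry the property name."""
        cached = self._energy_cache.get(seq)
        if cached is not None:
            return cached
        total = 0.0
        for w, (name, fn) in zip(self.weights, self.properties):
            try:
                total += w * float(fn(seq))
            except Exception as exc:
                raise RuntimeError(f"property {name!r} failed on {seq!r}: {exc}") from exc
        self._energy_cache[seq] = total
        return total

    def prior_logp(self, seq: str) -> float:
        cached = self._prior_cache.get(seq)
        if cached is None:
            cached = self._prior_cache[seq] = float(self.prior.logp(seq))
        return cached

    def log_unnorm_density(self, seq: str) -> float:
        """ln p_HUM(x) - E(x) * T^-1, up to the (never computed) ln Z."""
        return self.prior_logp(seq) - self.energy(seq) * self.inv_temperature

    def clear_cache(self) -> None:
        self._energy_cache.clear()
        self._prior_cache.clear()


def affinity_solubility_energy(
    affinity_fn: PropertyFn,
    solubility_fn: PropertyFn,
    w: float,
    inv_temperature: float = 10.0,
    prior: AutoregressivePrior | None = None,
) -> EnergyModel:
    """Canonical two-property model E = -w*f_aff - (1-w)*f_sol."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    return EnergyModel.from_objectives(
        objectives=[("affinity", affinity_fn), ("solubility", solubility_fn)],
        weights=[w, 1.0 - w],
        inv_temperature=inv_temperature,
        prior=prior,
    )
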