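"""Comparison generators: constrained hill-climbing and random mutants.

The local search mirrors the constrained-optimization comparator: many short
independent hill-climbing runs from the wild type, each proposing single
substitutions inside hard developability constraints (Hamming ball,
humanness cutoff, optional solubility floor) and accepting only strict
improvements of the affinity acquisition. The random-mutant control takes
the best training variant and scatters k substitutions at previously
unmutated positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .seqspace import ALPHABET, SearchConstraints, VariantSequence, WildType, hamming

Constraint = Callable[[str], bool]


@dataclass(frozen=True)
class LocalSearchConfig:
    n_runs: int = 800
    n_steps: int = 200
    proposal_subset: int = 20
    constraints: Sequence[Constraint] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_runs, self.n_steps, self.proposal_subset) <= 0:
            raise ValueError("counts must be positive")


def hamming_constraint(wt: WildType, d_lim: int) -> Constraint:
    return lambda seq: hamming(seq, wt.sequence) <= d_lim


def _hill_climb(
    objective: Callable[[str], float],
    wt: WildType,
    cfg: LocalSearchConfig,
    rng: np.random.Generator,
) -> str:
    """One run: best strict improvement over a sampled neighbor subset."""
    current = wt.sequence
    value = objective(current)
    L = len(current)
    for _ in range(cfg.n_steps):
        best_seq, best_val = None, value
        for _ in range(cfg.proposal_subset):
            pos = int(rng.integers(L))
            choices = [a for a in ALPHABET if a != current[pos]]
            letter = choices[int(rng.integers(len(choices)))]
            cand = current[:pos] + letter + current[pos + 1 :]
            if not all(ok(cand) for ok in cfg.constraints):
                continue
            v = objective(cand)
            if v > best_val:  # strict improvement only; plateaus rejected
                best_seq, best_val = cand, v
        if best_seq is None:
            continue
        current, value = best_seq, best_val
    return current


def local_search(
    cfg: LocalSearchConfig,
    objective: Callable[[str], float],
    wt: WildType,
) -> list[str]:
    """Final states of ``n_runs`` independent constrained hill-climbing runs."""
    if not all(ok(wt.sequence) for ok in cfg.constraints):
        raise ValueError("wild type violates a constraint")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    return [_hill_climb(objective, wt, cfg, np.random.default_rng(s)) for s in streams]


def random_mutants(
    best: str,
    wt: WildType,
    n: int = 500,
    k: int = 3,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """n sequences, each mutating ``best`` at k previously-unmutated positions.

    Substitution letters are uniform over the 19 alternatives to the current
    (wild-type) letter at each chosen position.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    variant = VariantSequence.from_wildtype(best, wt)
    mutated = {p for p, _ in variant.mutations}
    free = [i for i in range(len(best)) if i not in mutated]
    if k > len(free):
        raise ValueError(f"k={k} exceeds the {len(free)} unmutated positions")
    out = []
    for _ in range(n):
        positions = rng.choice(len(free), size=k, replace=False)
        seq = list(best)
        for fi in positions:
            pos = free[fi]
            choices = [a for a in ALPHABET if a != best[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        out.append("".join(seq))
    return out
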