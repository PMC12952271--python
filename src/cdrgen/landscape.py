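"""Ground-truth epistatic affinity landscapes and synthetic training data.

The true log-affinity of a variant is modeled with single-site fields and
pairwise couplings:

    f_aff(x) = f_aff(WT) + sum_i h_i(x_i) + sum_{i<j} J_ij(x_i, x_j),

with h_i(wt_i) = 0 and J_ij(a, b) = 0 whenever a or b is the wild-type
letter, so every term vanishes on the wild type. Two named parameterizations
set the difficulty: "simple" draws fields from N(-0.5, 0.5) and couplings
from N(0, 0.5); "hard" draws fields from N(0, 0.5) and couplings from
N(-0.5, 0.5), making random mutations deleterious mostly through
interactions, which single-mutant data cannot reveal.

The generated training table emulates a saturation-plus-random mutagenesis
library: all 660 enumerated single-substitution records (33 positions x 20
letters, identity substitutions kept as wild-type-affinity records), 2,100
random doubles and 11,900 random triples, each observed with N(0, 1)
measurement noise — 14,660 rows for the canonical 33-residue wild type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqspace import AA_INDEX, ALPHABET, WildType, hamming


@dataclass(frozen=True)
class LandscapeSpec:
    """Field/coupling Gaussian moments; ``simple`` and ``hard`` are canonical."""

    mode: str = "simple"
    h_mean: float = -0.5
    h_sd: float = 0.5
    j_mean: float = 0.0
    j_sd: float = 0.5

    @classmethod
    def simple(cls) -> "LandscapeSpec":
        return cls(mode="simple", h_mean=-0.5, h_sd=0.5, j_mean=0.0, j_sd=0.5)

    @classmethod
    def hard(cls) -> "LandscapeSpec":
        return cls(mode="hard", h_mean=0.0, h_sd=0.5, j_mean=-0.5, j_sd=0.5)

    @classmethod
    def named(cls, mode: str) -> "LandscapeSpec":
        if mode == "simple":
            return cls.simple()
        if mode == "hard":
            return cls.hard()
        raise ValueError(f"unknown landscape mode {mode!r}")


@dataclass(frozen=True)
class EpistasisLandscape:
    """Materialized fields h (L,20) and couplings J (L,L,20,20), upper pairs."""

    wt: WildType
    f_wt: float
    h: np.ndarray
    J: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        L = len(self.wt)
        if self.h.shape != (L, 20) or self.J.shape != (L, L, 20, 20):
            raise ValueError("field/coupling table shapes do not match wild type")

    def evaluate(self, seq: str) -> float:
        """f_wt + mutated-site fields + mutated-pair couplings."""
        wt = self.wt.sequence
        if len(seq) != len(wt):
            raise ValueError("sequence length differs from wild type")
        muts = [(i, AA_INDEX[a]) for i, (a, w) in enumerate(zip(seq, wt)) if a != w]
        total = self.f_wt
        for i, a in muts:
            total += self.h[i, a]
        for (i, a), (j, b) in itertools.combinations(muts, 2):
            total += self.J[i, j, a, b]
        return float(total)

    def evaluate_many(self, seqs) -> np.ndarray:
        return np.array([self.evaluate(s) for s in seqs])


def sample_landscape(
    spec: LandscapeSpec, wt: WildType, seed: int, f_wt: float = 0.0
) -> EpistasisLandscape:
    """Draw a landscape: non-WT entries i.i.d. Gaussian, WT entries exactly 0."""
    rng = np.random.default_rng(seed)
    L = len(wt)
    wt_idx = np.array([AA_INDEX[a] for a in wt.sequence])

    h = rng.normal(spec.h_mean, spec.h_sd, size=(L, 20))
    h[np.arange(L), wt_idx] = 0.0

    J = np.zeros((L, L, 20, 20))
    iu, ju = np.triu_indices(L, k=1)
    J[iu, ju] = rng.normal(spec.j_mean, spec.j_sd, size=(len(iu), 20, 20))
    # zero the WT rows/columns of every pair block
    for i, j in zip(iu, ju):
        J[i, j, wt_idx[i], :] = 0.0
        J[i, j, :, wt_idx[j]] = 0.0
    return EpistasisLandscape(wt=wt, f_wt=f_wt, h=h, J=J, seed=seed)


def nonwt_field_entries(ls: EpistasisLandscape) -> np.ndarray:
    """All h_i(a) with a != wt_i, flattened (the sampled field entries)."""
    wt_idx = np.array([AA_INDEX[a] for a in ls.wt.sequence])
    mask = np.ones_like(ls.h, dtype=bool)
    mask[np.arange(len(ls.wt)), wt_idx] = False
    return ls.h[mask]


def _random_k_mutant(wt: str, k: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(wt), size=k, replace=False)
    seq = list(wt)
    for p in positions:
        choices = [a for a in ALPHABET if a != wt[p]]
        seq[p] = choices[int(rng.integers(len(choices)))]
    return "".join(seq)


def build_dataset(
    ls: EpistasisLandscape,
    n_double: int = 2_100,
    n_triple: int = 11_900,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic training table: enumerated singles plus random doubles/triples.

    Singles enumerate every (position, letter) pair — L*20 rows including the
    identity substitutions, which record the wild-type affinity. Doubles and
    triples are distinct random k-mutants. ``observed_faff`` is the true
    landscape value plus N(0, noise_sd^2) noise.
    """
    wt = ls.wt.sequence
    L = len(wt)
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, int]] = []
    for i in range(L):
        for a in ALPHABET:
            seq = wt[:i] + a + wt[i + 1 :]
            rows.append((seq, hamming(seq, wt)))

    for k, n_req in ((2, n_double), (3, n_triple)):
        space = 1
        from math import comb

        space = comb(L, k) * 19**k
        if n_req > space:
            raise ValueError(f"cannot draw {n_req} distinct {k}-mutants from {space}")
        seen: set[str] = set()
        while len(seen) < n_req:
            s = _random_k_mutant(wt, k, rng)
            if s not in seen:
                seen.add(s)
                rows.append((s, k))

    seqs = [s for s, _ in rows]
    true = ls.evaluate_many(seqs)
    observed = true + rng.normal(0.0, noise_sd, size=len(seqs))
    return pd.DataFrame(
        {
            "sequence": seqs,
            "n_mutations": [m for _, m in rows],
            "true_faff": true,
            "observed_faff": observed,
        }
    )


def generate_negatives(
    wt: WildType, n: int, ka: float = 1e7, seed: int = 0
) -> pd.DataFrame:
    """Random fully-scrambled CDRs assigned one fixed weak affinity.

    Every position is i.i.d. uniform over the 20 letters; each record gets
    the affinity implied by the association constant: faff = log10(Ka * 1 nM)
    with Ka in 1/M, i.e. Kd = 1/Ka (Ka = 1e7 -> Kd = 100 nM -> faff = -2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(wt)
    letters = np.array(list(ALPHABET))
    seqs = ["".join(letters[rng.integers(0, 20, size=L)]) for _ in range(n)]
    faff = float(np.log10(ka * 1e-9))
    return pd.DataFrame({"sequence": seqs, "faff": faff})
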