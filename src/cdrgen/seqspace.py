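"""Sequence domain types, mutation neighborhoods and sequence-level metrics.

The design region is a fixed-length window of concatenated heavy-chain CDRs
(H1+H2+H3). Candidate variants live in the Hamming ball of radius ``d_lim``
around the wild type; the canonical search space for a 33-residue window and
``d_lim = 6`` contains C(33,6) * 20**6 ~ 7.1e13 sequences, far beyond
exhaustive search, which is why the package samples instead of enumerating.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Concatenated CDRH1/H2/H3 of the Ab-14 heavy chain (33 residues), the
#: wild-type design region used throughout.
AB14_CDR_WT = "GFTLNSYGISIYSDGRRTFYGDSVGRAAGTFDS"

#: Per-residue charge contributions: +1 for R/K, +0.1 for H, -1 for D/E.
CHARGE_WEIGHTS = {"R": 1.0, "K": 1.0, "H": 0.1, "D": -1.0, "E": -1.0}


class InvalidSequenceError(ValueError):
    """Raised for sequences outside the 20-letter amino-acid alphabet."""


def validate_sequence(seq: str) -> str:
    if not seq:
        raise InvalidSequenceError("empty sequence")
    for i, a in enumerate(seq):
        if a not in AA_INDEX:
            raise InvalidSequenceError(f"invalid amino acid {a!r} at position {i}")
    return seq


@dataclass(frozen=True)
class WildType:
    """The reference sequence mutations are counted against."""

    sequence: str
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.region_labels is not None and len(self.region_labels) != len(self.sequence):
            raise ValueError("region_labels length must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSequence:
    """A candidate sequence plus its mutation set relative to the wild type.

    ``mutations`` is a frozenset of ``(position, amino_acid)`` with 0-based
    positions; its size equals the Hamming distance to the wild type.
    """

    sequence: str
    mutations: frozenset[tuple[int, str]] = field(default_factory=frozenset)

    @classmethod
    def from_wildtype(cls, sequence: str, wt: WildType) -> "VariantSequence":
        validate_sequence(sequence)
        if len(sequence) != len(wt):
            raise ValueError("variant length differs from wild type")
        muts = frozenset(
            (i, a) for i, (a, w) in enumerate(zip(sequence, wt.sequence)) if a != w
        )
        return cls(sequence=sequence, mutations=muts)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


@dataclass(frozen=True)
class SearchConstraints:
    """Hard limits on the mutation neighborhood."""

    d_lim: int = 6
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        if self.d_lim < 0:
            raise ValueError("d_lim must be non-negative")


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def neighborhood_size(x: str, wt: WildType, c: SearchConstraints) -> int:
    """Number of legal single-substitution moves from ``x``.

    Strictly inside the ball every position admits 19 substitutions; on the
    boundary (distance == d_lim) only already-mutated positions may change,
    so the neighborhood shrinks to ``19 * d_lim``. The sampler uses this
    count for its Hastings correction.
    """
    d = hamming(x, wt.sequence)
    if d > c.d_lim:
        raise ValueError("sequence outside the d_lim ball")
    n_mutable = len(x) if d < c.d_lim else d
    return (len(c.alphabet) - 1) * n_mutable


def random_neighbor(
    x: VariantSequence, wt: WildType, c: SearchConstraints, rng: np.random.Generator
) -> VariantSequence:
    """Uniform draw from the single-substitution neighborhood of ``x``.

    The neighborhood is the set of sequences exactly one substitution from
    ``x`` and at most ``d_lim`` substitutions from the wild type. Each
    eligible position contributes the same number (19) of moves, so sampling
    position-then-letter uniformly is uniform over the neighborhood.
    """
    d = x.n_mutations
    if d > c.d_lim:
        raise ValueError("start sequence outside the d_lim ball")
    if d < c.d_lim:
        pos = int(rng.integers(len(x.sequence)))
    else:
        mutated = sorted(p for p, _ in x.mutations)
        pos = mutated[int(rng.integers(len(mutated)))]
    current = x.sequence[pos]
    choices = [a for a in c.alphabet if a != current]
    letter = choices[int(rng.integers(len(choices)))]
    seq = x.sequence[:pos] + letter + x.sequence[pos + 1 :]
    return VariantSequence.from_wildtype(seq, wt)


def count_search_space(
    L: int, d: int, alphabet_size: int = 20, mode: str = "exact-d-positions"
) -> int:
    """Size of the mutational design space around a length-``L`` wild type.

    ``exact-d-positions`` counts variants obtained by choosing ``d`` of the
    ``L`` positions and placing any of the ``alphabet_size`` letters at each
    chosen position: C(L,d) * alphabet_size**d. ``up-to-d`` counts distinct
    sequences within Hamming distance ``d``:
    sum_k C(L,k) * (alphabet_size-1)**k.
    """
    if not 0 <= d <= L:
        raise ValueError("require 0 <= d <= L")
    if mode == "exact-d-positions":
        return math.comb(L, d) * alphabet_size**d
    if mode == "up-to-d":
        return sum(math.comb(L, k) * (alphabet_size - 1) ** k for k in range(d + 1))
    raise ValueError(f"unknown mode {mode!r}")


def diversity(seqs: Sequence[str]) -> float:
    """Mean pairwise Hamming distance over ordered pairs of a generated set."""
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity requires at least 2 sequences")
    total = sum(hamming(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1 :])
    return 2.0 * total / (n * (n - 1))


def novelty(seqs: Sequence[str], ref: Sequence[str]) -> float:
    """Mean over the set of the minimum Hamming distance to a reference set."""
    if not ref:
        raise ValueError("reference set must be non-empty")
    if not seqs:
        raise ValueError("sequence set must be non-empty")
    return float(np.mean([min(hamming(s, r) for r in ref) for s in seqs]))


def overlap(a: Iterable[str], b: Iterable[str]) -> float:
    """|A & B| / min(|A|,|B|) on de-duplicated sequence sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap requires non-empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


def charge_score(seq: str) -> float:
    """Heuristic net-charge score; the developable band is [-2, 2]."""
    validate_sequence(seq)
    return sum(CHARGE_WEIGHTS.get(a, 0.0) for a in seq)


def _default_diwv() -> Mapping[str, Mapping[str, float]]:
    from Bio.SeqUtils import ProtParamData

    return ProtParamData.DIWV


def instability_index(
    seq: str, table: Mapping[str, Mapping[str, float]] | None = None
) -> float:
    """Dipeptide-weight instability index; values above 40 suggest instability.

    (10/L) * sum over consecutive dipeptides of the published dipeptide
    instability weight. Unknown dipeptides contribute weight 1.0 with a
    logged warning so non-canonical tables degrade loudly, not silently.
    """
    validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    diwv = table if table is not None else _default_diwv()
    total = 0.0
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        try:
            total += diwv[a][b]
        except KeyError:
            log.warning("unknown dipeptide %s%s, using weight 1.0", a, b)
            total += 1.0
    return 10.0 / len(seq) * total
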