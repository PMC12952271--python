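"""Autoregressive humanness prior p_HUM.

The generative target weights candidates by the likelihood an autoregressive
model of natural human heavy-chain repertoires assigns to them,
p_HUM(x) = prod_i p(x_i | x_<i). Transformer repertoire models are not
shipped; the package provides (a) a trainable desk-scale categorical prior
(position-specific or k-mer autoregressive) with additive smoothing, (b) a
uniform prior under which the Boltzmann target reduces to the
maximum-entropy form, and (c) a file-backed adapter serving externally
computed log-likelihoods under the same contract. All log-probabilities are
natural log (the conventional humanness cutoff ln p >= -120 is on ln p).
"""

from __future__ import annotations

import math
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

from .seqspace import AA_INDEX, ALPHABET, validate_sequence


class AutoregressivePrior(Protocol):
    def logp(self, seq: str) -> float: ...

    def per_token(self, seq: str) -> np.ndarray: ...


class UniformPrior:
    """i.i.d. uniform letters: logp = L * ln(1/20)."""

    def per_token(self, seq: str) -> np.ndarray:
        validate_sequence(seq)
        return np.full(len(seq), -math.log(len(ALPHABET)))

    def logp(self, seq: str) -> float:
        return float(self.per_token(seq).sum())


class CategoricalPrior:
    """Position-specific categorical prior: independent conditionals per site.

    ``probs`` is (L, 20), each row a normalized distribution.
    """

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(ALPHABET):
            raise ValueError("probs must be (L, 20)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each positional distribution must sum to 1")
        self.probs = probs

    def per_token(self, seq: str) -> np.ndarray:
        validate_sequence(seq)
        if len(seq) != self.probs.shape[0]:
            raise ValueError("sequence length differs from prior length")
        idx = np.array([AA_INDEX[a] for a in seq])
        return np.log(self.probs[np.arange(len(seq)), idx])

    def logp(self, seq: str) -> float:
        return float(self.per_token(seq).sum())


class KmerPrior:
    """k-mer autoregressive prior: p(x_i | previous k letters), smoothed.

    Contexts never seen in training fall back to the smoothed marginal of
    the pseudocount (uniform).
    """

    def __init__(self, k: int, counts: dict[str, np.ndarray], pseudocount: float):
        self.k = k
        self.counts = counts
        self.pseudocount = pseudocount

    def _conditional(self, context: str) -> np.ndarray:
        c = self.counts.get(context, np.zeros(len(ALPHABET)))
        c = c + self.pseudocount
        return c / c.sum()

    def per_token(self, seq: str) -> np.ndarray:
        validate_sequence(seq)
        out = np.empty(len(seq))
        for i, a in enumerate(seq):
            ctx = seq[max(0, i - self.k) : i]
            out[i] = math.log(self._conditional(ctx)[AA_INDEX[a]])
        return out

    def logp(self, seq: str) -> float:
        return float(self.per_token(seq).sum())


class TablePrior:
    """File-backed adapter: sequence -> ln p table (CSV: sequence, logp).

    Shares the scoring contract of the trainable priors; per-token
    conditionals are not stored, so only whole-sequence logp is served.
    """

    def __init__(self, table: dict[str, float]):
        self.table = table

    @classmethod
    def from_csv(cls, path) -> "TablePrior":
        df = pd.read_csv(path)
        return cls(dict(zip(df["sequence"], df["logp"].astype(float))))

    def logp(self, seq: str) -> float:
        try:
            return float(self.table[seq])
        except KeyError:
            raise KeyError(f"no stored log-probability for sequence {seq!r}")

    def per_token(self, seq: str) -> np.ndarray:
        raise NotImplementedError("file-backed prior stores whole-sequence logp only")


def fit_categorical_prior(
    sequences: Iterable[str],
    pseudocount: float = 1.0,
    order: str = "position-specific",
    k: int = 2,
) -> AutoregressivePrior:
    """Fit a smoothed categorical prior from training sequences.

    ``position-specific`` requires an aligned same-length set and estimates
    one distribution per site; ``k-mer`` estimates p(x_i | previous k
    letters) pooled over positions, usable on variable-length input.
    """
    seqs = [validate_sequence(s) for s in sequences]
    if not seqs:
        raise ValueError("empty training set")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if order == "position-specific":
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("position-specific prior requires equal-length sequences")
        counts = np.zeros((L, len(ALPHABET)))
        for s in seqs:
            for i, a in enumerate(s):
                counts[i, AA_INDEX[a]] += 1
        counts += pseudocount
        return CategoricalPrior(counts / counts.sum(axis=1, keepdims=True))
    if order == "k-mer":
        counts: dict[str, np.ndarray] = {}
        for s in seqs:
            for i, a in enumerate(s):
                ctx = s[max(0, i - k) : i]
                counts.setdefault(ctx, np.zeros(len(ALPHABET)))[AA_INDEX[a]] += 1
        return KmerPrior(k, counts, max(pseudocount, 1e-12))
    raise ValueError(f"unknown order {order!r}")


def humanness_filter(prior: AutoregressivePrior, seq: str, threshold: float) -> bool:
    """True iff ln p_HUM(x) >= threshold (inclusive, per the >= convention)."""
    return prior.logp(seq) >= threshold
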