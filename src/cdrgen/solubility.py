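"""Sequence-based solubility score.

f_sol(x) = -sum_j SASA(j, x_j) * HW(x_j) + const: each residue contributes
its (relative) solvent exposure times a hydrophobicity weight, so buried or
hydrophilic residues cost little and exposed hydrophobic residues are
penalized. Higher score = more soluble. SASA values are relative exposures
normalized to Ala-X-Ala maxima and come from a pluggable provider; the
structure-trained per-residue SASA predictor itself is outside this package
and enters through the ``file`` provider as precomputed vectors.

The hydrophobicity weight table is configuration. The shipped default is the
Kyte-Doolittle hydropathy scale — a documented literature placeholder, not
the privately fitted weights the score was originally calibrated with, so
absolute score magnitudes are configuration-dependent (rankings under a
fixed table are what the generative process consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .seqspace import ALPHABET, validate_sequence

#: Kyte-Doolittle hydropathy values (literature default; positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass(frozen=True)
class HydrophobicityWeights:
    """Per-amino-acid hydrophobicity weights; all 20 letters required."""

    hw: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in ALPHABET if a not in self.hw]
        if missing:
            raise ValueError(f"missing hydrophobicity weights for {missing}")
        for a in ALPHABET:
            if not np.isfinite(self.hw[a]):
                raise ValueError(f"non-finite weight for {a}")

    @classmethod
    def default(cls) -> "HydrophobicityWeights":
        return cls(dict(KYTE_DOOLITTLE))

    @classmethod
    def from_csv(cls, path) -> "HydrophobicityWeights":
        df = pd.read_csv(path)
        return cls(dict(zip(df["amino_acid"], df["weight"].astype(float))))

    def __getitem__(self, a: str) -> float:
        return float(self.hw[a])


@dataclass(frozen=True)
class SASAProvider:
    """sequence -> per-residue relative SASA vector (>= 0, same length)."""

    name: str
    predict: Callable[[str], np.ndarray] = field(repr=False)

    def __call__(self, seq: str) -> np.ndarray:
        out = np.asarray(self.predict(seq), dtype=float)
        if out.shape != (len(seq),):
            raise ValueError(
                f"SASA provider {self.name!r} returned length {out.shape} "
                f"for a length-{len(seq)} sequence"
            )
        if np.any(out < 0):
            raise ValueError("SASA values must be non-negative")
        return out


def sasa_provider(kind: str, source=None) -> SASAProvider:
    """Build a SASA provider.

    ``constant``: every residue fully exposed (1.0) — the HW-only ablation.
    ``table``: a fixed per-amino-acid mean exposure, from a CSV
    (amino_acid, sasa) or a mapping; without a source a neutral 0.5 is used.
    ``file``: stored per-residue vectors keyed by sequence, from a CSV
    (sequence, position, sasa); unknown sequences are an error, never a
    silent fallback.
    """
    if kind == "constant":
        return SASAProvider("constant", lambda seq: np.ones(len(seq)))
    if kind == "table":
        if source is None:
            table = {a: 0.5 for a in ALPHABET}
        elif isinstance(source, Mapping):
            table = {a: float(v) for a, v in source.items()}
        else:
            df = pd.read_csv(source)
            table = dict(zip(df["amino_acid"], df["sasa"].astype(float)))
        return SASAProvider("table", lambda seq: np.array([table[a] for a in seq]))
    if kind == "file":
        if source is None:
            raise ValueError("file provider requires a source path")
        df = pd.read_csv(source)
        store = {
            seq: np.asarray(g.sort_values("position")["sasa"], dtype=float)
            for seq, g in df.groupby("sequence")
        }

        def predict(seq: str) -> np.ndarray:
            try:
                return store[seq]
            except KeyError:
                raise KeyError(f"no stored SASA vector for sequence {seq!r}")

        return SASAProvider("file", predict)
    raise ValueError(f"unknown SASA provider kind {kind!r}")


def write_sasa_file(path, vectors: Mapping[str, np.ndarray]) -> None:
    """Write per-residue SASA vectors in the CSV layout the file provider reads."""
    rows = [
        {"sequence": seq, "position": i, "sasa": float(v)}
        for seq, vec in vectors.items()
        for i, v in enumerate(vec)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def solubility_score(
    seq: str,
    sasa: SASAProvider | None = None,
    hw: HydrophobicityWeights | None = None,
    const: float = 0.0,
) -> float:
    """-sum_j SASA(j, x_j) * HW(x_j) + const; higher = more soluble."""
    validate_sequence(seq)
    if sasa is None:
        sasa = sasa_provider("constant")
    if hw is None:
        hw = HydrophobicityWeights.default()
    exposure = sasa(seq)
    weights = np.array([hw[a] for a in seq])
    return const - float(exposure @ weights)


def make_solubility_fn(
    sasa: SASAProvider | None = None,
    hw: HydrophobicityWeights | None = None,
    const: float = 0.0,
) -> Callable[[str], float]:
    """Close over a provider/weights pair for use as an energy-model property."""
    sasa = sasa or sasa_provider("constant")
    hw = hw or HydrophobicityWeights.default()
    return lambda seq: solubility_score(seq, sasa, hw, const)
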