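"""Sequence-to-vector encoders feeding the GP kernel.

The default encoder is the position-major, alphabet-minor one-hot layout
(length L*20). External protein-language-model embeddings enter only through
a file-backed encoder serving precomputed vectors, or a user-registered
callable; no model weights are shipped or downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .seqspace import AA_INDEX, ALPHABET, InvalidSequenceError


@dataclass(frozen=True)
class Encoder:
    """A deterministic sequence -> fixed-length real vector map."""

    name: str
    dimension: int
    encode: Callable[[str], np.ndarray] = field(repr=False)

    def __call__(self, seq: str) -> np.ndarray:
        return self.encode(seq)

    def encode_many(self, seqs) -> np.ndarray:
        return np.stack([self.encode(s) for s in seqs])


def encode_onehot(seq: str) -> np.ndarray:
    """One-hot encode a sequence: position-major, alphabet-minor, length L*20.

    Exactly L entries are 1; the squared Euclidean distance between two
    encodings is twice their Hamming distance, so the RBF kernel on one-hot
    vectors is a function of Hamming distance alone.
    """
    vec = np.zeros(len(seq) * len(ALPHABET))
    for i, a in enumerate(seq):
        try:
            vec[i * len(ALPHABET) + AA_INDEX[a]] = 1.0
        except KeyError:
            raise InvalidSequenceError(f"invalid amino acid {a!r} at position {i}")
    return vec


def onehot_encoder(length: int) -> Encoder:
    return Encoder(name="onehot", dimension=length * len(ALPHABET), encode=encode_onehot)


def file_backed_encoder(path, name: str = "file") -> Encoder:
    """Encoder serving precomputed vectors from a TSV table.

    First column is the sequence; remaining columns are vector components.
    Unknown sequences raise KeyError — no silent fallback.
    """
    df = pd.read_csv(path, sep="\t")
    seq_col = df.columns[0]
    table = {
        str(row[seq_col]): np.asarray(row.iloc[1:], dtype=float)
        for _, row in df.iterrows()
    }
    dim = len(df.columns) - 1

    def encode(seq: str) -> np.ndarray:
        try:
            return table[seq]
        except KeyError:
            raise KeyError(f"no precomputed embedding for sequence {seq!r}")

    return Encoder(name=name, dimension=dim, encode=encode)


def write_embedding_table(path, seqs, vectors) -> None:
    """Write a sequence -> vector TSV readable by :func:`file_backed_encoder`."""
    vectors = np.asarray(vectors, dtype=float)
    cols = {"sequence": list(seqs)}
    for j in range(vectors.shape[1]):
        cols[f"v{j}"] = vectors[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


_REGISTRY: dict[str, Encoder] = {}


def register_encoder(enc: Encoder) -> None:
    if enc.name in _REGISTRY:
        raise ValueError(f"encoder {enc.name!r} already registered")
    _REGISTRY[enc.name] = enc


def get_encoder(name: str) -> Encoder:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no encoder registered under {name!r}")
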