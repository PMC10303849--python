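"""One-hot encoding of DNA sequences and reverse complementation.

Sequences are encoded as L x 4 binary matrices with column order A, C, G, T.
Sequences containing N are rejected (never imputed) and counted in a discard
log, matching the training convention of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SequenceAlphabetError(ValueError):
    """A character outside {A, C, G, T, N} was encountered."""


class SequenceContainsN(ValueError):
    """The sequence contains one or more N characters and was rejected."""


@dataclass
class OneHotSequence:
    """An L x 4 one-hot matrix (columns A, C, G, T) with its identifier."""

    matrix: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"one-hot matrix must be L x 4, got {self.matrix.shape}")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiscardLog:
    """Tally of sequences rejected during encoding (N-containing)."""

    n_discarded: int = 0
    ids: list = field(default_factory=list)

    def record(self, seq_id: str) -> None:
        self.n_discarded += 1
        self.ids.append(seq_id)


def one_hot_encode(sequence: str, seq_id: str = "") -> OneHotSequence:
    """Encode a DNA string as an L x 4 binary matrix (columns A, C, G, T).

    Case-insensitive. Sequences containing N raise :class:`SequenceContainsN`
    (callers batch-encoding a dataset catch this and log the discard); any
    other character raises :class:`SequenceAlphabetError` naming the character
    and its position.
    """
    seq = sequence.upper()
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    for i, base in enumerate(seq):
        if base == "N":
            raise SequenceContainsN(
                f"sequence {seq_id or '<unnamed>'} contains N at position {i}"
            )
        idx = _BASE_INDEX.get(base)
        if idx is None:
            raise SequenceAlphabetError(
                f"invalid character {base!r} at position {i} in sequence "
                f"{seq_id or '<unnamed>'}"
            )
        mat[i, idx] = 1.0
    return OneHotSequence(matrix=mat, id=seq_id)


def encode_batch(
    sequences, ids=None, discard_log: DiscardLog | None = None
) -> tuple[np.ndarray, list, DiscardLog]:
    """Encode equal-length sequences into an (N, L, 4) array.

    N-containing sequences are dropped and recorded in the returned
    :class:`DiscardLog`; the list of surviving ids is returned alongside.
    """
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    log = discard_log if discard_log is not None else DiscardLog()
    mats, kept = [], []
    for seq, sid in zip(sequences, ids):
        try:
            mats.append(one_hot_encode(seq, sid).matrix)
        except SequenceContainsN:
            log.record(sid)
        else:
            kept.append(sid)
    if not mats:
        return np.zeros((0, 0, 4)), kept, log
    lengths = {m.shape[0] for m in mats}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    return np.stack(mats), kept, log


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement (an involution on DNA strings)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def reverse_complement_onehot(batch: np.ndarray) -> np.ndarray:
    """Reverse complement of (..., L, 4) one-hot arrays.

    Reversing the position axis and swapping A<->T, C<->G is equivalent to
    reversing both trailing axes under column order A, C, G, T.
    """
    return batch[..., ::-1, ::-1].copy()
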