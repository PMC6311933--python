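"""One-hot encoding of sequence windows with symmetric zero padding.

Channel order is (A, C, G, U); N maps to an all-zero column.  Each side
of the sequence receives ``floor(filter_size_1 / 2)`` zero columns so the
first convolution layer sees every real position in full context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGU"
_INDEX = {base: i for i, base in enumerate(ALPHABET)}


class EncodingError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,U,N}."""


@dataclass
class EncodedSequence:
    """One-hot matrix of shape (4, pad + L + pad) with its pad width."""

    matrix: np.ndarray
    pad: int
    origin: str | None = None

    @property
    def core_length(self) -> int:
        return self.matrix.shape[1] - 2 * self.pad


def pad_width(filter_size_1: int) -> int:
    return filter_size_1 // 2


def encode(sequence: str, filter_size_1: int, origin: str | None = None) -> EncodedSequence:
    """One-hot encode `sequence`, flanked by floor(filter_size_1/2) zero columns."""
    pad = pad_width(filter_size_1)
    length = len(sequence)
    matrix = np.zeros((4, length + 2 * pad), dtype=np.float64)
    for offset, base in enumerate(sequence):
        if base == "N":
            continue
        try:
            matrix[_INDEX[base], pad + offset] = 1.0
        except KeyError:
            raise EncodingError(
                f"invalid character {base!r} at offset {offset}; "
                "expected one of A, C, G, U, N"
            ) from None
    return EncodedSequence(matrix=matrix, pad=pad, origin=origin)


def decode(encoded: EncodedSequence) -> str:
    """Invert :func:`encode`; all-zero core columns decode to N."""
    core = encoded.matrix[:, encoded.pad : encoded.matrix.shape[1] - encoded.pad]
    sums = core.sum(axis=0)
    bad = np.nonzero(sums > 1)[0]
    if bad.size:
        raise EncodingError(f"malformed column {int(bad[0])}: sum > 1")
    out = []
    for col in range(core.shape[1]):
        if sums[col] == 0:
            out.append("N")
        else:
            out.append(ALPHABET[int(core[:, col].argmax())])
    return "".join(out)


def encode_batch(
    sequences: list[str], filter_size_1: int
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a batch, right-padding to the longest sequence.

    Returns (X, lengths) where X has shape (N, 4, 2*pad + max_len) and
    lengths holds each sequence's true (unpadded) length.  Length-aware
    layers downstream must ignore columns beyond ``2*pad + length``.
    """
    pad = pad_width(filter_size_1)
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    width = 2 * pad + (int(lengths.max()) if len(sequences) else 0)
    x = np.zeros((len(sequences), 4, width), dtype=np.float64)
    for i, seq in enumerate(sequences):
        enc = encode(seq, filter_size_1)
        x[i, :, : enc.matrix.shape[1]] = enc.matrix
    return x, lengths
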