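"""One-hot encoding of flanked sequence windows.

Column order is fixed as (A, U/T, G, C).  A window position that lies
outside the available mRNA context (an absent flank position) is encoded
as a uniform 0.05 row rather than a basis vector, so the convolutional
stage sees a weak, non-committal signal there instead of a hard zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sirnadeep.records_io import ABSENT, GUIDE_LEN

#: Fixed column order of the one-hot matrix; persisted in model metadata.
BASE_ORDER = ("A", "U", "G", "C")
ABSENT_VALUE = 0.05

_BASE_VECS = {
    "A": np.array([1.0, 0.0, 0.0, 0.0]),
    "U": np.array([0.0, 1.0, 0.0, 0.0]),
    "T": np.array([0.0, 1.0, 0.0, 0.0]),
    "G": np.array([0.0, 0.0, 1.0, 0.0]),
    "C": np.array([0.0, 0.0, 0.0, 1.0]),
    ABSENT: np.full(4, ABSENT_VALUE),
}


@dataclass
class EncodedSequence:
    """(21+2n)×4 matrix of one-hot rows with 0.05-filled absent rows."""

    matrix: np.ndarray
    n: int
    absent_mask: np.ndarray

    def __post_init__(self) -> None:
        L = GUIDE_LEN + 2 * self.n
        if self.matrix.shape != (L, 4):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({L}, 4)")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def decode(self) -> str:
        """Recover the window string (absent rows become the sentinel)."""
        out = []
        for row, absent in zip(self.matrix, self.absent_mask):
            if absent:
                out.append(ABSENT)
            else:
                out.append(BASE_ORDER[int(np.argmax(row))])
        return "".join(out)


def encode_base(symbol: str, position: int | None = None) -> np.ndarray:
    """Map one nucleotide (or the absent sentinel) to its 4-vector.

    A=(1,0,0,0), U/T=(0,1,0,0), G=(0,0,1,0), C=(0,0,0,1); the absent
    sentinel maps to (0.05, 0.05, 0.05, 0.05).
    """
    try:
        return _BASE_VECS[symbol.upper()].copy()
    except (KeyError, AttributeError):
        where = "" if position is None else f" at position {position}"
        raise ValueError(f"unknown symbol {symbol!r}{where}") from None


def encode_window(window: str, n: int) -> EncodedSequence:
    """Encode a 21+2n window (with absent marks) into an EncodedSequence."""
    L = GUIDE_LEN + 2 * n
    if len(window) != L:
        raise ValueError(f"window length {len(window)} != 21 + 2*{n} = {L}")
    matrix = np.empty((L, 4))
    absent = np.zeros(L, dtype=bool)
    for i, sym in enumerate(window):
        matrix[i] = encode_base(sym, position=i)
        absent[i] = sym == ABSENT
    return EncodedSequence(matrix=matrix, n=n, absent_mask=absent)
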