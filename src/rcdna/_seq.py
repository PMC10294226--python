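"""Nucleotide <-> small-integer helpers.

The canonical 2-bit code is A=00, T=01, C=10, G=11, so the integer index of
a base equals its 2-bit value and XOR of indices equals bitwise XOR of the
2-bit codes.  G and C are the two indices >= 2, which makes GC counting a
single comparison.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

BASES = "ATCG"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def seq_to_indices(seq: str) -> np.ndarray:
    """Map an ACGT string to a uint8 array of 2-bit base values."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _CODE[raw]
    if idx.size and idx.max() > 3:
        bad = seq[int(np.argmax(idx > 3))]
        raise AlphabetError(f"invalid base {bad!r}; expected one of A/C/G/T")
    return idx


def indices_to_seq(idx: np.ndarray) -> str:
    return _DECODE[np.asarray(idx, dtype=np.uint8)].tobytes().decode("ascii")


def as_indices(seq) -> np.ndarray:
    """Accept either a string or an index array (validated)."""
    if isinstance(seq, str):
        return seq_to_indices(seq)
    idx = np.asarray(seq, dtype=np.uint8)
    if idx.size and idx.max() > 3:
        raise AlphabetError("base indices must be in 0..3")
    return idx
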