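"""Hexamer encoding shared by the fragment simulator and the bias estimator.

The hexamer attributed to a Tn5 cut at position ``p`` is the reference-strand
sequence on the half-open window ``[p - 3, p + 3)`` — a symmetric window
centred on the midpoint of the 9-bp duplicated overhang.  The simulator and
the estimator must agree on this registration constant, so it lives here.
"""

from __future__ import annotations

import numpy as np

K = 6
#: cut position p maps to the hexamer on [p - FLANK, p + FLANK)
FLANK = 3
N_HEXAMERS = 4**K

_BASES = "ACGT"
_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_WEIGHTS = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A/C/G/T (case-insensitive) to 0..3; anything else to -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def hexamer_index(hexamer: str) -> int:
    """Integer id of a 6-mer (AAAAAA = 0 ... TTTTTT = 4095)."""
    if len(hexamer) != K:
        raise ValueError(f"expected a {K}-mer, got {hexamer!r}")
    codes = encode_sequence(hexamer)
    if (codes < 0).any():
        raise ValueError(f"non-ACGT base in {hexamer!r}")
    return int(codes @ _WEIGHTS)


def hexamer_from_index(index: int) -> str:
    if not 0 <= index < N_HEXAMERS:
        raise ValueError(f"hexamer index out of range: {index}")
    out = []
    for _ in range(K):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def hexamer_ids(sequence: str) -> np.ndarray:
    """Per-position hexamer id for every cut position in ``sequence``.

    Returns an int64 array of ``len(sequence)`` where entry ``p`` is the id of
    ``sequence[p-3:p+3]``, or -1 where that window exits the sequence or
    contains a non-ACGT base.
    """
    codes = encode_sequence(sequence)
    n = codes.size
    ids = np.full(n, -1, dtype=np.int64)
    if n < K:
        return ids
    windows = np.lib.stride_tricks.sliding_window_view(codes, K)
    vals = windows @ _WEIGHTS
    bad = (windows < 0).any(axis=1)
    vals[bad] = -1
    # window starting at s is centred on cut position s + FLANK
    ids[FLANK : FLANK + vals.size] = vals
    return ids
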