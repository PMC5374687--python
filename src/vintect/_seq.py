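"""Low-level DNA sequence helpers shared across the package.

Sequences are plain upper-case Python strings over ACGTN. For numeric
kernels they are encoded as int8 arrays with A,C,G,T -> 0..3 and N -> 4;
code 4 mismatches every base, including another N.
"""
from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 256-entry lookup: byte value of base -> 2-bit code, N/other -> 4
_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _c in zip(b"ACGT", range(4)):
    _ENCODE_LUT[_b] = _c
for _b, _c in zip(b"acgt", range(4)):
    _ENCODE_LUT[_b] = _c

_DECODE = np.array(list("ACGTN"))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an int8 array (A,C,G,T=0..3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes of an encoded sequence.

    Returns ``(values, valid)`` where ``values[i]`` is the 2k-bit integer
    code of the k-mer starting at ``i`` and ``valid[i]`` is False when the
    window contains an N. Requires 2k <= 62.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    weights = (1 << (2 * np.arange(k - 1, -1, -1, dtype=np.int64)))
    clean = np.where(windows == 4, 0, windows).astype(np.int64)
    values = clean @ weights
    valid = ~(windows == 4).any(axis=1)
    return values, valid
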