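"""Encoded DNA helpers.

Sequences are held as ``numpy.uint8`` arrays with A,C,G,T -> 0,1,2,3 and any
other character mapped to the sentinel 255 (treated as unalignable/invalid).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
INVALID = np.uint8(255)

_ENCODE_LUT = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE = np.array(list(BASES + "N"), dtype="U1")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string to a uint8 array (non-ACGT -> 255)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE_LUT[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 array back to a string (255 -> 'N')."""
    idx = np.where(arr == INVALID, 4, arr).astype(np.intp)
    return "".join(_DECODE[idx])


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence; 255 stays 255."""
    out = arr[::-1].copy()
    valid = out != INVALID
    out[valid] = 3 - out[valid]
    return out


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random encoded sequence."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)
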