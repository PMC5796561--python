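"""Integer k-mer encoding utilities shared by the mapper, CRISPR detector and spacer matcher.

DNA is encoded base-per-byte (A=0, C=1, G=2, T=3, anything else 4) and k-mers
are packed into unsigned integers (2 bits per base, k <= 31), so window codes
are exact: two windows share a code iff they are the same string.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: sentinel code for windows containing non-ACGT characters
INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes 0..3 (4 for ambiguous bases)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement (case preserved, N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def window_codes(codes: np.ndarray, k: int, chunk: int = 4_000_000) -> np.ndarray:
    """Pack every length-``k`` window of ``codes`` into a uint64.

    Windows containing an ambiguous base get :data:`INVALID`. ``k`` must be
    <= 31 so the packed value fits 62 bits. Output length is
    ``len(codes) - k + 1`` (empty if the input is shorter than ``k``).
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    out = np.empty(n, dtype=np.uint64)
    # chunked so the (windows x k) intermediate stays small on long scaffolds
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        view = np.lib.stride_tricks.sliding_window_view(codes[lo : hi + k - 1], k)
        vals = (view.astype(np.uint64) * powers).sum(axis=1)
        bad = (view > 3).any(axis=1)
        vals[bad] = INVALID
        out[lo:hi] = vals
    return out


def kmer_code(seq: str) -> np.uint64:
    """Pack one k-mer (len <= 31) into a uint64; INVALID if it has ambiguity codes."""
    codes = encode(seq)
    if (codes > 3).any():
        return INVALID
    powers = np.uint64(4) ** np.arange(len(codes) - 1, -1, -1, dtype=np.uint64)
    return np.uint64((codes.astype(np.uint64) * powers).sum())
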