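"""Low-level DNA sequence utilities shared across the package.

Sequences exist in two representations: Python strings over the A/C/G/T
alphabet at the API surface, and 2-bit-coded ``uint8`` arrays (A=0, C=1,
G=2, T=3) inside the vectorised kernels.  The numeric coding is chosen so
that packing a barcode big-endian into an integer preserves lexicographic
order, which makes count-table ordering deterministic for free.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

# complement under the 2-bit coding: A<->T (0<->3), C<->G (1<->2)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

_COMP_STR = str.maketrans("ACGT", "TGCA")


def is_dna(seq: str) -> bool:
    """True iff *seq* is a (possibly empty) uppercase A/C/G/T string."""
    return all(c in BASES for c in seq)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a ``uint8`` array (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.size and codes.max() > 3:
        bad = seq[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for a 1-D code array."""
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def encode_many(seqs, length: int) -> np.ndarray:
    """Encode an iterable of equal-length DNA strings to an ``(n, length)`` matrix."""
    joined = "".join(seqs)
    if len(joined) % max(length, 1) and length > 0:
        raise ValueError("sequences are not all of the stated length")
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.size and codes.max() > 3:
        raise ValueError("non-ACGT character in sequence set")
    n = 0 if length == 0 else raw.size // length
    return codes.reshape(n, length)


def decode_matrix(mat: np.ndarray) -> np.ndarray:
    """Decode an ``(n, k)`` code matrix to an array of ``k``-mer strings."""
    n, k = mat.shape
    if n == 0:
        return np.empty(0, dtype=f"U{max(k, 1)}")
    ascii_mat = np.ascontiguousarray(_DECODE_LUT[mat])
    return ascii_mat.view(f"S{k}").ravel().astype(f"U{k}")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP_STR)[::-1]


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Row-wise reverse complement of a code matrix."""
    return _COMP[mat][:, ::-1]


def pack(mat: np.ndarray) -> np.ndarray:
    """Pack an ``(n, k)`` code matrix into big-endian base-4 integers.

    Lexicographic order of the k-mers equals numeric order of the codes.
    Supports k up to 31.
    """
    n, k = mat.shape
    if k > 31:
        raise ValueError("k-mer too long to pack into int64")
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return mat.astype(np.int64) @ weights


def unpack(codes: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`pack`: integers back to an ``(n, k)`` code matrix."""
    codes = np.asarray(codes, dtype=np.int64)
    mat = np.empty((codes.size, k), dtype=np.uint8)
    rem = codes.copy()
    for j in range(k - 1, -1, -1):
        mat[:, j] = (rem & 3).astype(np.uint8)
        rem >>= 2
    return mat
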