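"""Sequence encoding utilities shared across the package.

Bases are stored as ``uint8`` codes: A=0, C=1, G=2, T=3, N=4.  Dinucleotides
use the code ``4 * first + second`` giving the fixed ordering
AA, AC, AG, AT, CA, ..., TT that every 16-vector in the package follows.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)
DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

_CODE_TO_CHAR = np.frombuffer(b"ACGTN", dtype=np.uint8)

# lookup table over the full byte range; 255 marks an invalid character
_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _CHAR_TO_CODE[ord(_c)] = _i
    _CHAR_TO_CODE[ord(_c.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(sequence: str | bytes) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes.

    Case-insensitive; accepts A, C, G, T and N.  Any other character raises
    ``ValueError`` naming the first offending position.
    """
    if isinstance(sequence, str):
        raw = sequence.encode("ascii", errors="surrogateescape")
    else:
        raw = bytes(sequence)
    arr = np.frombuffer(raw, dtype=np.uint8)
    codes = _CHAR_TO_CODE[arr]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"non-IUPAC character {chr(arr[pos])!r} at position {pos}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _CODE_TO_CHAR[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[np.asarray(codes, dtype=np.uint8)][::-1]


def revcomp_str(sequence: str) -> str:
    return decode(reverse_complement(encode(sequence)))


def dinuc_code(xy: str) -> int:
    """Index of dinucleotide ``xy`` in the canonical 16-vector ordering."""
    try:
        return DINUC_INDEX[xy.upper()]
    except KeyError:
        raise ValueError(f"not a dinucleotide over ACGT: {xy!r}") from None
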