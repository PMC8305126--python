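"""Shared low-level sequence helpers.

All DNA is handled as uppercase ACGT strings at module boundaries; hot
numeric paths use uint8 arrays with the encoding A=0, C=1, G=2, T=3
(complement is then ``3 - x``).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 256-entry lookup: ASCII byte -> base index, 255 for non-ACGT.
_CHAR2INT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _CHAR2INT[ord(_c)] = _i
    _CHAR2INT[ord(_c.lower())] = _i

_INT2CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings (no indels)."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode ACGT string as uint8 array (A=0..T=3).

    Raises ValueError on ambiguous/non-ACGT characters.
    """
    arr = _CHAR2INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr


def ints_to_seq(arr: np.ndarray) -> str:
    """Decode uint8 base indices back to an ACGT string."""
    return _INT2CHAR[arr].tobytes().decode("ascii")


def revcomp_ints(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return ints_to_seq(rng.integers(0, 4, size=n, dtype=np.uint8))


def encode_phred(quals: np.ndarray) -> str:
    """Phred scores -> Phred+33 ASCII string."""
    return (np.asarray(quals, dtype=np.uint8) + 33).tobytes().decode("ascii")


def decode_phred(qual_str: str) -> np.ndarray:
    """Phred+33 ASCII string -> int16 Phred scores."""
    return (
        np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    )


def chrom_sort_key(chrom: str):
    """Sort chromosome names numerically when possible (1,2,...,22,X,Y,...)."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)
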