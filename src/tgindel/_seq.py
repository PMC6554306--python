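"""Low-level DNA sequence helpers shared across the package.

Sequences are handled in two forms: Python strings over {A,C,G,T} at API
boundaries, and uint8 code arrays (A=0, C=1, G=2, T=3, 4=separator/other)
inside the numeric kernels.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

ALPHABET = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def check_dna(seq: str, what: str = "sequence") -> None:
    if (encode(seq) > 3).any():
        raise ValueError(f"{what} contains characters outside A/C/G/T")
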