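"""Low-level DNA sequence helpers shared across the package.

Sequences are plain upper-case strings over {A,C,G,T,N,X}; the numeric
encoding maps A,C,G,T to 0..3 and every other character to 4, which never
matches anything in the alignment kernels.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtnXx", "TGCANtgcanXx")

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement; N and X are self-complementary."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def validate_dna(seq: str, name: str = "sequence", alphabet: str = "ACGTN") -> str:
    """Upper-case and check a sequence against an alphabet; raises ValueError."""
    s = seq.upper()
    bad = set(s) - set(alphabet)
    if bad:
        raise ValueError(
            f"{name} contains characters outside {alphabet}: {sorted(bad)!r}"
        )
    return s
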