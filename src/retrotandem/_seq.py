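"""Shared nucleotide-sequence helpers: validation, encoding, reverse complement."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
A, C, G, T, N = range(5)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# purines A,G -> 0 ; pyrimidines C,T -> 1 ; N -> -1 (never comparable)
_PURINE_PYRIMIDINE = np.array([0, 1, 0, 1, -1], dtype=np.int8)


def clean(seq: str, *, name: str = "sequence") -> str:
    """Uppercase-normalize *seq* and reject characters outside {A,C,G,T,N}."""
    s = seq.upper()
    bad = set(s) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"{name} contains characters outside {{A,C,G,T,N}}: {sorted(bad)!r}"
        )
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a clean sequence as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    if not seq:
        return np.empty(0, dtype=np.uint8)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for ch, code in _CODE.items():
        out[arr == ord(ch)] = code
    if (out == 255).any():
        raise ValueError("sequence not clean; call clean() first")
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(x: int, y: int) -> bool:
    """A<->G or C<->T (both purines or both pyrimidines, and different)."""
    return x != y and _PURINE_PYRIMIDINE[x] == _PURINE_PYRIMIDINE[y] >= 0
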