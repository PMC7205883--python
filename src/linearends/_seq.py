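"""Small shared sequence helpers (plain strings over {A,C,G,T})."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# numeric encoding used by the mapper / read simulator
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMP)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 array with A,C,G,T -> 0..3."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA of length n at the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))
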