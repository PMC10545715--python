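"""Byte-level sequence helpers shared across the pipeline.

Sequences are held as numpy uint8 arrays of ASCII codes (A/C/G/T/N) so
that comparison and pileup accumulation vectorise. Coordinates are
0-based half-open throughout the library; SAM/VCF/GFF writers convert.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = (ord(x) for x in "ACGTN")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII code -> 0..3 index (N and anything else -> 4)
CODE_OF = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(BASES):
    CODE_OF[b] = i

_COMP = np.arange(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y


def seq_to_array(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode()
    return np.frombuffer(bytes(seq).upper(), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def random_genome(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. bases at the requested GC content (no repeat structure)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def phred_to_error(q: np.ndarray | float):
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def error_to_phred(e: float, cap: int = 40) -> int:
    if e <= 0:
        return cap
    return int(min(cap, round(-10.0 * np.log10(e))))
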