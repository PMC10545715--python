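"""Sequence variants (substitutions and short indels) in a VCF-like
left-anchored normal form, plus apply/lift machinery.

A variant is anchored at a 0-based reference position:
  * substitution: ref "A"  -> alt "G"            (len 1 -> len 1)
  * insertion:    ref "A"  -> alt "A" + inserted (anchor base retained)
  * deletion:     ref "A"+deleted -> alt "A"
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import array_to_seq, seq_to_array


@dataclass(frozen=True, order=True)
class Variant:
    pos: int  # 0-based anchor on the reference
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def ref_span(self) -> int:
        return len(self.ref)

    @property
    def length_delta(self) -> int:
        return len(self.alt) - len(self.ref)


def check_disjoint(variants: list[Variant], genome_len: int) -> None:
    last_end = -1
    for v in sorted(variants):
        if v.pos < 0 or v.pos + v.ref_span > genome_len:
            raise ValueError(f"variant at {v.pos} outside genome bounds")
        if v.pos <= last_end:
            raise ValueError(f"overlapping variants near position {v.pos}")
        last_end = v.pos + v.ref_span - 1


def apply_variants(genome: np.ndarray, variants: list[Variant]) -> np.ndarray:
    """Return the derived (strain) genome with all variants applied.

    Raises if any variant's REF does not match the genome, or variants
    overlap — truth consistency is a hard contract, not a best effort.
    """
    check_disjoint(variants, len(genome))
    pieces: list[np.ndarray] = []
    cursor = 0
    for v in sorted(variants):
        ref_here = array_to_seq(genome[v.pos : v.pos + v.ref_span])
        if ref_here != v.ref:
            raise ValueError(
                f"variant REF mismatch at {v.pos}: expected {v.ref!r}, "
                f"genome has {ref_here!r}"
            )
        pieces.append(genome[cursor : v.pos])
        pieces.append(seq_to_array(v.alt))
        cursor = v.pos + v.ref_span
    pieces.append(genome[cursor:])
    return np.concatenate(pieces)


class CoordinateLift:
    """Maps reference coordinates to coordinates on the variant-applied
    genome (piecewise-constant offset between indels)."""

    def __init__(self, variants: list[Variant], genome_len: int):
        pos, delta = [0], [0]
        running = 0
        for v in sorted(variants):
            if v.length_delta != 0:
                running += v.length_delta
                # offset takes effect after the variant's reference span
                pos.append(v.pos + v.ref_span)
                delta.append(running)
        self._pos = np.asarray(pos)
        self._delta = np.asarray(delta)
        self.genome_len = genome_len
        self.derived_len = genome_len + running

    def lift(self, x: int) -> int:
        i = int(np.searchsorted(self._pos, x, side="right")) - 1
        return int(np.clip(x + self._delta[i], 0, self.derived_len))

    def lift_interval(self, start: int, end: int) -> tuple[int, int]:
        a, b = self.lift(start), self.lift(end)
        if b < a:
            b = a
        return a, b
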