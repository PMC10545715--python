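"""Sliding-window quality trimming.

Scans each read 5'->3' with a fixed-size window (default 3 nt) and
truncates at the first window whose mean Phred falls below the quality
threshold; any read left shorter than the minimum length (default 36 nt)
is discarded, and by default its mate is dropped with it so that pairing
invariants stay simple.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class TrimReport:
    input_pairs: int
    surviving_pairs: int
    dropped_pairs: int
    truncated_mates: int

    def as_dict(self):
        return dict(
            input_pairs=self.input_pairs,
            surviving_pairs=self.surviving_pairs,
            dropped_pairs=self.dropped_pairs,
            truncated_mates=self.truncated_mates,
        )


def trimmed_length(
    qual: np.ndarray, window: int = 3, quality_threshold: float = 15.0
) -> int:
    """Length kept after truncating at the first failing window."""
    L = len(qual)
    if L < window:
        return L
    cs = np.concatenate([[0.0], np.cumsum(qual, dtype=float)])
    means = (cs[window:] - cs[:-window]) / window
    fail = means < quality_threshold
    idx = int(np.argmax(fail))
    if not fail[idx]:
        return L
    return idx  # truncate before the failing window's first base


def _lengths_matrix(
    qual: np.ndarray, lens: np.ndarray, window: int, thr: float
) -> np.ndarray:
    n, L = qual.shape
    if n == 0 or L < window:
        return lens.copy()
    q = qual.astype(float).copy()
    # mask positions beyond each read's current length with a high value
    col = np.arange(L)[None, :]
    q[col >= lens[:, None]] = 1e6
    cs = np.cumsum(q, axis=1)
    means = (cs[:, window - 1 :] - np.concatenate(
        [np.zeros((n, 1)), cs[:, : L - window]], axis=1
    )) / window
    fail = means < thr
    any_fail = fail.any(axis=1)
    first = np.argmax(fail, axis=1)
    out = lens.copy()
    out[any_fail] = np.minimum(first[any_fail], lens[any_fail])
    return out


def trim_batch(
    batch,
    window: int = 3,
    min_len: int = 36,
    quality_threshold: float = 15.0,
    drop_pair: bool = True,
):
    """Trim a ReadBatch; returns (trimmed batch, TrimReport).

    With drop_pair=True (default) a pair is removed whenever either mate
    falls below min_len; otherwise the surviving orphan is kept and the
    failing mate's length is set to 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_len < window:
        raise ValueError("min_len must be >= window")
    if batch.seq1.shape[0] != batch.seq2.shape[0]:
        raise ValueError(
            f"mismatched mate counts in sample {batch.sample!r}: "
            f"{batch.seq1.shape[0]} vs {batch.seq2.shape[0]}"
        )
    new1 = _lengths_matrix(batch.qual1, batch.len1, window, quality_threshold)
    new2 = _lengths_matrix(batch.qual2, batch.len2, window, quality_threshold)
    truncated = int((new1 < batch.len1).sum() + (new2 < batch.len2).sum())
    short1, short2 = new1 < min_len, new2 < min_len
    if drop_pair:
        keep = ~(short1 | short2)
    else:
        keep = ~(short1 & short2)
        new1[short1] = 0
        new2[short2] = 0
    idx = np.nonzero(keep)[0]
    trimmed = replace(
        batch,
        ids=[batch.ids[i] for i in idx],
        seq1=batch.seq1[idx],
        qual1=batch.qual1[idx],
        seq2=batch.seq2[idx],
        qual2=batch.qual2[idx],
        len1=new1[idx],
        len2=new2[idx],
    )
    report = TrimReport(
        input_pairs=batch.n_pairs,
        surviving_pairs=int(keep.sum()),
        dropped_pairs=int((~keep).sum()),
        truncated_mates=truncated,
    )
    return trimmed, report
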