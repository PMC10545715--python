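"""Affine-gap dynamic programming for end-to-end read placement.

Semantics: the read is aligned globally (every read base is consumed, no
soft clipping) while the reference acts as a free-ended template — the
alignment may start and end anywhere ("fit" alignment, Gotoh affine
recurrences). A gap of length g costs gap_open + g * gap_extend, i.e. the
first gap base costs open+extend and each further base costs extend.

All scores are integer-valued, so float equality in the traceback is
exact. The row-wise formulation vectorises over the reference axis; the
reference-gap state uses the affine closed form
    D[i,j] = open + ext*j + max_{k<j}(G[i,k] - ext*k)
evaluated with a running maximum.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def substitution_scores(
    read: np.ndarray,
    ref: np.ndarray,
    match: float,
    mismatch: float,
    allow: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """(m, n) score matrix; `allow` maps reference offsets to extra bases
    treated as match-equivalent there (the SNP-aware index contract)."""
    S = np.where(read[:, None] == ref[None, :], float(match), float(mismatch))
    if allow:
        for j, codes in allow.items():
            if 0 <= j < S.shape[1]:
                S[np.isin(read, codes), j] = match
    return S


def _forward(S: np.ndarray, gap_open: float, gap_ext: float, keep: bool):
    m, n = S.shape
    j_idx = np.arange(n + 1, dtype=float)
    M = np.zeros(n + 1)  # row 0: free start anywhere on the reference
    I = np.full(n + 1, NEG)
    D = np.full(n + 1, NEG)
    if keep:
        Ms, Is, Ds = [M.copy()], [I.copy()], [D.copy()]
    for i in range(1, m + 1):
        prev_all = np.maximum(np.maximum(M, I), D)
        Mi = np.full(n + 1, NEG)
        Mi[1:] = S[i - 1] + prev_all[:-1]
        Ii = np.maximum(np.maximum(M, D) + gap_open + gap_ext, I + gap_ext)
        G = np.maximum(Mi, Ii)
        c = G - gap_ext * j_idx
        run = np.empty(n + 1)
        run[0] = NEG
        np.maximum.accumulate(c[:-1], out=run[1:])
        Di = gap_open + gap_ext * j_idx + run
        Di[0] = NEG
        M, I, D = Mi, Ii, Di
        if keep:
            Ms.append(M.copy()); Is.append(I.copy()); Ds.append(D.copy())
    if keep:
        return np.array(Ms), np.array(Is), np.array(Ds)
    return M, I, D


def fit_score(S: np.ndarray, gap_open: float, gap_ext: float) -> float:
    """Best fit-alignment score (trailing reference positions free; a
    terminal reference gap is never beneficial, so D is excluded)."""
    if S.shape[0] == 0:
        return 0.0
    M, I, _D = _forward(S, gap_open, gap_ext, keep=False)
    return float(np.maximum(M, I).max())


def fit_align(
    S: np.ndarray, gap_open: float, gap_ext: float
) -> tuple[float, int, int, str]:
    """Best fit alignment with traceback.

    Returns (score, ref_start, ref_end, cigar) where [ref_start, ref_end)
    is the consumed reference interval and cigar uses M/I/D with I = read
    base not in the reference (insertion), D = reference base skipped.
    """
    m, n = S.shape
    Ms, Is, Ds = _forward(S, gap_open, gap_ext, keep=True)
    finals = np.maximum(Ms[m], Is[m])
    j = int(finals.argmax())
    score = float(finals[j])
    state = "M" if Ms[m, j] >= Is[m, j] else "I"
    oe = gap_open + gap_ext
    i = m
    ops: list[str] = []
    while i > 0:
        if state == "M":
            ops.append("M")
            prev = (Ms[i - 1, j - 1], Ds[i - 1, j - 1], Is[i - 1, j - 1])
            target = Ms[i, j] - (
                S[i - 1, j - 1] if j >= 1 else NEG
            )
            i, j = i - 1, j - 1
            if prev[0] == target:
                state = "M"
            elif prev[1] == target:
                state = "D"
            else:
                state = "I"
            if i == 0:
                break
        elif state == "I":
            ops.append("I")
            if Is[i, j] == Is[i - 1, j] + gap_ext:
                state = "I"
            elif Is[i, j] == Ms[i - 1, j] + oe:
                state = "M"
            else:
                state = "D"
            i -= 1
            if i == 0:
                break
        else:  # D: same-row transition consuming reference
            ops.append("D")
            if Ds[i, j] == Ds[i, j - 1] + gap_ext:
                state = "D"
            elif Ds[i, j] == Ms[i, j - 1] + oe:
                state = "M"
            else:
                state = "I"
            j -= 1
    ref_start = j
    # find ref_end: initial j (before walk) was consumed interval end
    # recompute: consumed ref = count of M/D ops
    consumed = sum(1 for o in ops if o in "MD")
    ref_end = ref_start + consumed
    ops.reverse()
    cigar = _compress(ops)
    return score, ref_start, ref_end, cigar


def _compress(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def cigar_read_len(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "MI")


def cigar_ref_len(cigar: str) -> int:
    return sum(n for n, op in cigar_ops(cigar) if op in "MD")
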