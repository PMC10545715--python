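"""Independent brute-force reference implementations used to validate the
package's fast paths. Deliberately simple (triple loops, exhaustive
enumeration) and kept free of any package internals beyond data types.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = float("-inf")


def brute_fit_score(
    read: np.ndarray,
    ref: np.ndarray,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_ext: float,
) -> float:
    """Exhaustive affine-gap fit alignment: plain-Python Gotoh over the
    whole reference with free reference ends; gap of length g costs
    gap_open + g*gap_ext."""
    m, n = len(read), len(ref)
    oe = gap_open + gap_ext
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0
    for i in range(1, m + 1):
        for j in range(n + 1):
            if j >= 1:
                s = match if read[i - 1] == ref[j - 1] else mismatch
                M[i][j] = s + max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1])
            I[i][j] = max(M[i - 1][j] + oe, I[i - 1][j] + gap_ext, D[i - 1][j] + oe)
            if j >= 1:
                D[i][j] = max(M[i][j - 1] + oe, I[i][j - 1] + oe, D[i][j - 1] + gap_ext)
    return max(max(M[m][j], I[m][j]) for j in range(n + 1))


def brute_best_placement(
    read: np.ndarray,
    genome: dict[str, np.ndarray],
    match: float,
    mismatch: float,
    gap_open: float,
    gap_ext: float,
    revcomp,
) -> float:
    """Best fit score over both strands of every reference sequence."""
    best = NEG
    for seq in genome.values():
        for s in (read, revcomp(read)):
            best = max(
                best, brute_fit_score(s, seq, match, mismatch, gap_open, gap_ext)
            )
    return best


def brute_upgma(D: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Average-linkage agglomeration by explicit enumeration of all
    pairwise mean distances between current clusters; tie-break on the
    lexicographically smallest sorted pair of smallest member leaves."""
    n = len(D)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = float(
                np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
            )
            rep = tuple(sorted((min(clusters[a]), min(clusters[b]))))
            key = (d, rep)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _rep), a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        merges.append((min(a, b), max(a, b), d, len(merged)))
        clusters[next_id] = merged
        next_id += 1
    return merges


def brute_davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    uniq = sorted(set(labels.tolist()))
    cents = {c: X[labels == c].mean(axis=0) for c in uniq}
    S = {
        c: float(
            np.mean(np.linalg.norm(X[labels == c] - cents[c], axis=1))
        )
        for c in uniq
    }
    total = 0.0
    for i in uniq:
        worst = NEG
        for j in uniq:
            if i == j:
                continue
            mij = float(np.linalg.norm(cents[i] - cents[j]))
            ratio = (S[i] + S[j]) / mij if mij > 0 else float("inf")
            worst = max(worst, ratio)
        total += worst
    return total / len(uniq)


def brute_venn_regions(sets: dict[str, set]) -> dict[frozenset, int]:
    """Region counts by scanning every element of the universe."""
    universe = set().union(*sets.values())
    out: dict[frozenset, int] = {}
    names = list(sets)
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            out[frozenset(inside)] = 0
    for x in universe:
        membership = frozenset(t for t in names if x in sets[t])
        if membership:
            out[membership] += 1
    return out
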