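"""Minimal unspliced seed-and-extend aligner with the score-threshold and
unique-mapping contracts of the original mapping stage.

A read is placed by exact k-mer seeding at regularly spaced offsets, then
each candidate locus is verified: an ungapped comparison when it suffices
(with the gap cost open+extend = 8 > mismatch 6, a gapped alignment can
only beat an ungapped one that has at least two mismatches, so the fast
path is exact), otherwise a windowed affine-gap DP. A placement is
emitted only when its score reaches the length-dependent threshold
f(L) = A + B*L (defaults A=-4, B=-0.5); reads with more than one
best-scoring locus are flagged non-unique and excluded downstream.

Synthetic genomes are intron-free, so the aligner is deliberately
unspliced; coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dp import fit_align, fit_score, substitution_scores
from .sequences import revcomp


@dataclass(frozen=True)
class ScoreParams:
    match: int = 0
    mismatch_penalty: int = -6
    gap_open: int = -5
    gap_extend: int = -3
    threshold_const: float = -4.0   # A in f(L) = A + B*L
    threshold_slope: float = -0.5   # B
    seed_len: int = 20
    band_pad: int = 16              # DP window slack around a candidate locus
    max_candidates: int = 64
    max_hits_per_seed: int = 32

    def __post_init__(self):
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.threshold_slope > 0:
            raise ValueError("threshold slope must be <= 0 (non-increasing f)")
        if self.seed_len < 8:
            raise ValueError("seed length must be >= 8")

    def min_score(self, read_len: int) -> float:
        return self.threshold_const + self.threshold_slope * read_len


@dataclass
class AlignmentRecord:
    read_id: str
    mate: int
    reference_id: str
    position: int          # 0-based leftmost
    strand: str            # "+" / "-"
    cigar: str
    score: float
    is_unique: bool
    mapping_count: int
    seq: np.ndarray        # bases in reference orientation
    qual: np.ndarray       # Phred values, same orientation

    @property
    def ref_end(self) -> int:
        from .dp import cigar_ref_len

        return self.position + cigar_ref_len(self.cigar)


@dataclass
class PairedRead:
    read_id: str
    seq1: np.ndarray
    qual1: np.ndarray
    seq2: np.ndarray
    qual2: np.ndarray


@dataclass
class PairAlignment:
    read_id: str
    rec1: AlignmentRecord | None
    rec2: AlignmentRecord | None

    @property
    def is_mapped(self) -> bool:
        """Pair counts as mapped when at least one mate placed uniquely."""
        return any(r is not None and r.is_unique for r in (self.rec1, self.rec2))

    def unique_records(self) -> list[AlignmentRecord]:
        return [r for r in (self.rec1, self.rec2) if r is not None and r.is_unique]


class KmerIndex:
    """Exact k-mer -> position lookup per reference sequence. Both strands
    are served by querying the read and its reverse complement against the
    forward index."""

    def __init__(self, genome: dict[str, np.ndarray], k: int = 20):
        if k < 8:
            raise ValueError("k must be >= 8")
        if not genome:
            raise ValueError("empty genome")
        self.k = k
        self.genome = genome
        self._maps: dict[str, dict[bytes, list[int]]] = {}
        for name, seq in genome.items():
            if len(seq) < k:
                warnings.warn(
                    f"sequence {name!r} shorter than k={k}: unplaceable"
                )
                self._maps[name] = {}
                continue
            table: dict[bytes, list[int]] = {}
            raw = seq.tobytes()
            for i in range(len(raw) - k + 1):
                table.setdefault(raw[i : i + k], []).append(i)
            self._maps[name] = table

    def lookup(self, kmer: bytes):
        for name, table in self._maps.items():
            hits = table.get(kmer)
            if hits:
                yield name, hits

    def views(self, ref_id: str, start: int, end: int):
        """Window views to score a candidate against: (ref_window, allow).

        The plain index exposes a single literal window with no extra
        match-equivalent bases.
        """
        return [(self.genome[ref_id][start:end], None)]


class SnpAwareIndex(KmerIndex):
    """Index over a corrected genome that additionally registers residual
    multi-allelic substitutions and indels: a read base matching any
    registered alternate incurs no mismatch penalty, and a registered
    indel is traversable without gap penalty (served as an alternative
    window haplotype with the indel applied).
    """

    def __init__(
        self,
        genome: dict[str, np.ndarray],
        substitutions: dict[str, dict[int, np.ndarray]] | None = None,
        indels: dict[str, list] | None = None,
        k: int = 20,
    ):
        super().__init__(genome, k)
        self.substitutions = substitutions or {}
        self.indels = indels or {}  # ref_id -> list[Variant]

    def views(self, ref_id: str, start: int, end: int):
        window = self.genome[ref_id][start:end]
        subs = self.substitutions.get(ref_id, {})
        allow = {
            pos - start: codes
            for pos, codes in subs.items()
            if start <= pos < end
        }
        out = [(window, allow or None)]
        for v in self.indels.get(ref_id, ()):  # one indel per extra view
            if not (start <= v.pos and v.pos + v.ref_span <= end):
                continue
            local = v.pos - start
            alt = np.frombuffer(v.alt.encode(), dtype=np.uint8)
            hap = np.concatenate(
                [window[:local], alt, window[local + v.ref_span :]]
            )
            # allow entries left of the indel keep their offsets
            hap_allow = {j: c for j, c in allow.items() if j < local} or None
            out.append((hap, hap_allow))
        return out


def _effective_mismatches(
    read: np.ndarray, window: np.ndarray, offset: int, allow
) -> int | None:
    L = len(read)
    if offset < 0 or offset + L > len(window):
        return None
    diff = np.nonzero(window[offset : offset + L] != read)[0]
    if allow is None or len(diff) == 0:
        return len(diff)
    mm = 0
    for d in diff:
        codes = allow.get(offset + int(d))
        if codes is None or read[d] not in codes:
            mm += 1
    return mm


def align_read(
    seq: np.ndarray,
    qual: np.ndarray,
    index: KmerIndex,
    params: ScoreParams,
    read_id: str = "",
    mate: int = 1,
) -> AlignmentRecord | None:
    """Best placement of one read, or None when no placement reaches the
    score threshold. Non-unique best placements are reported with
    mapping_count > 1 and is_unique False."""
    L = len(seq)
    k = index.k
    if L < k:
        return None
    thr = params.min_score(L)

    # seed offsets: non-overlapping plus a terminal seed
    offs = list(range(0, L - k + 1, k))
    if offs[-1] != L - k:
        offs.append(L - k)

    oriented = {"+": seq, "-": revcomp(seq)}
    candidates: list[tuple[str, str, int]] = []
    seen = set()
    for strand, s in oriented.items():
        raw = s.tobytes()
        for off in offs:
            for ref_id, hits in index.lookup(raw[off : off + k]):
                for p in hits[: params.max_hits_per_seed]:
                    key = (strand, ref_id, p - off)
                    if key not in seen:
                        seen.add(key)
                        candidates.append(key)
    if not candidates:
        return None
    candidates.sort()
    candidates = candidates[: params.max_candidates]

    pad = params.band_pad
    scored: list[tuple[float, str, str, int, int]] = []  # score,strand,ref,ws,cand
    for strand, ref_id, cand in candidates:
        ref_len = len(index.genome[ref_id])
        ws = max(0, cand - pad)
        we = min(ref_len, cand + L + pad)
        if we - ws < L:
            # allow partial-window DP only if read could still fit with gaps
            if we - ws < L - pad:
                continue
        s = oriented[strand]
        best_here = -np.inf
        for window, allow in index.views(ref_id, ws, we):
            mm = _effective_mismatches(s, window, cand - ws, allow)
            if mm is not None:
                u = mm * params.mismatch_penalty
                if mm <= 1:  # gapped alignment cannot beat this
                    best_here = max(best_here, u)
                    continue
            else:
                u = -np.inf
            S = substitution_scores(
                s, window, params.match, params.mismatch_penalty, allow
            )
            g = fit_score(S, params.gap_open, params.gap_extend)
            best_here = max(best_here, u, g)
        scored.append((best_here, strand, ref_id, ws, cand))

    best = max(t[0] for t in scored)
    if best < thr:
        return None

    # resolve distinct best placements (tie margin 0: exact score ties only)
    placements: dict[tuple[str, str, int], tuple[int, str]] = {}
    for score, strand, ref_id, ws, cand in scored:
        if score != best:
            continue
        s = oriented[strand]
        ref_len = len(index.genome[ref_id])
        we = min(ref_len, cand + L + pad)
        chosen = None
        for window, allow in index.views(ref_id, ws, we):
            mm = _effective_mismatches(s, window, cand - ws, allow)
            if mm is not None and mm * params.mismatch_penalty == best:
                chosen = (cand, f"{L}M")
                break
            S = substitution_scores(
                s, window, params.match, params.mismatch_penalty, allow
            )
            g, tb_start, _tb_end, cigar = fit_align(
                S, params.gap_open, params.gap_extend
            )
            if g == best:
                chosen = (ws + tb_start, cigar)
                break
        if chosen is not None:
            placements.setdefault((strand, ref_id, chosen[0]), chosen)

    n_loci = max(len(placements), 1)
    (strand, ref_id, pos), (pos_, cigar) = sorted(placements.items())[0]
    if strand == "-":
        out_seq, out_qual = revcomp(seq), qual[::-1]
    else:
        out_seq, out_qual = seq, qual
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        reference_id=ref_id,
        position=pos,
        strand=strand,
        cigar=cigar,
        score=best,
        is_unique=(n_loci == 1),
        mapping_count=n_loci,
        seq=out_seq,
        qual=out_qual,
    )


def align_pair(
    pair: PairedRead, index: KmerIndex, params: ScoreParams
) -> PairAlignment:
    """Mates are aligned independently; concordance is not enforced."""
    r1 = align_read(pair.seq1, pair.qual1, index, params, pair.read_id, 1)
    r2 = align_read(pair.seq2, pair.qual2, index, params, pair.read_id, 2)
    return PairAlignment(pair.read_id, r1, r2)


def align_pairs(
    pairs: list[PairedRead], index: KmerIndex, params: ScoreParams
) -> list[PairAlignment]:
    return [align_pair(p, index, params) for p in pairs]


def pairs_from_batch(batch) -> list[PairedRead]:
    """Flatten a simulated/trimmed ReadBatch into per-pair views."""
    out = []
    for i, rid in enumerate(batch.ids):
        l1, l2 = int(batch.len1[i]), int(batch.len2[i])
        out.append(
            PairedRead(
                rid,
                batch.seq1[i, :l1],
                batch.qual1[i, :l1],
                batch.seq2[i, :l2],
                batch.qual2[i, :l2],
            )
        )
    return out


def mapping_rate(alignments: list[PairAlignment]) -> float:
    """Uniquely mapped mates over all mates."""
    total = 2 * len(alignments)
    if total == 0:
        return 0.0
    mapped = sum(len(pa.unique_records()) for pa in alignments)
    return mapped / total
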