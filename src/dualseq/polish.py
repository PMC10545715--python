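"""Iterative single-nucleotide correction of a strain-divergent reference.

The loop re-expresses the classic polish cycle from first principles:
map reads -> pileup -> Phred-scaled site call -> conditional base
replacement -> re-map against the corrected genome. A site is corrected
only when its Phred-scaled quality exceeds the threshold (strictly
greater than 5.0 by default) AND exactly one alternate substitution
allele is supported; multi-allelic substitutions and indels are never
applied to the sequence — they are routed into the final SNP-aware index
instead, where any registered allele is match-equivalent.

Site quality model: bases are independent; a base with Phred Q is wrong
with probability e = 10^(-Q/10), uniformly over the three other bases.
With a flat prior over the four haploid genotypes,
  QUAL = -10 * log10 P(reference genotype | observed bases),
so a single supporting alternate read at Phred Q yields
QUAL = Q + 10*log10(3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import (
    AlignmentRecord,
    KmerIndex,
    PairedRead,
    ScoreParams,
    SnpAwareIndex,
    align_pairs,
    mapping_rate,
)
from .dp import cigar_ops
from .sequences import BASES, CODE_OF
from .variants import Variant

LOG10_3 = float(np.log10(3.0))

# log10(1 - 10^(-q/10)) per Phred value; Phred 0 clamped to 1.
_LOG1ME = np.empty(128)
for _q in range(128):
    _e = 10.0 ** (-max(_q, 1) / 10.0)
    _LOG1ME[_q] = np.log10(1.0 - _e)


@dataclass
class PileupColumn:
    reference_id: str
    position: int
    ref_base: str
    base_counts: dict[str, int]
    base_qual_sums: dict[str, float]      # sum of Phred values per base
    base_log1me_sums: dict[str, float]    # sum of log10(1 - e) per base

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


@dataclass
class VariantCall:
    reference_id: str
    position: int            # 0-based
    ref: str
    alts: list[str]
    qual: float
    applied: bool = False

    @property
    def n_alts(self) -> int:
        return len(self.alts)

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return not self.is_substitution


@dataclass
class IterationStats:
    detected: int
    applied: int
    mapping_rate: float


@dataclass
class PolishReport:
    iterations: list[IterationStats] = field(default_factory=list)
    stage_mapping_rates: dict[str, float] = field(default_factory=dict)
    final_multi_alt_snps: int = 0
    final_indels: int = 0


class Pileup:
    """Per-reference stacked base evidence with vectorised accumulation.

    Stores sufficient statistics (count, sum of Phred, sum of
    log10(1-e)) per base per site — the genotype posterior depends on the
    observations only through these sums. Insertions are attached to the
    left anchor site; deleted reference columns receive no base."""

    def __init__(self, genome: dict[str, np.ndarray]):
        self.genome = genome
        self.counts = {r: np.zeros((4, len(s)), dtype=np.int32)
                       for r, s in genome.items()}
        self.qsum = {r: np.zeros((4, len(s))) for r, s in genome.items()}
        self.lsum = {r: np.zeros((4, len(s))) for r, s in genome.items()}
        self.indel_obs: dict[tuple[str, int, str, str], int] = {}
        self.n_skipped = 0  # non-ACGT read bases

    def add_records(self, records: list[AlignmentRecord]) -> None:
        simple: dict[str, list[AlignmentRecord]] = {}
        for rec in records:
            if rec.reference_id not in self.genome:
                raise KeyError(
                    f"alignment references unknown sequence {rec.reference_id!r}"
                )
            L = len(rec.seq)
            if rec.cigar == f"{L}M":
                simple.setdefault(rec.reference_id, []).append(rec)
            else:
                self._add_gapped(rec)
        for ref, recs in simple.items():
            codes = np.concatenate([CODE_OF[r.seq] for r in recs])
            quals = np.concatenate([r.qual for r in recs]).astype(np.int64)
            pos = np.concatenate(
                [np.arange(r.position, r.position + len(r.seq)) for r in recs]
            )
            ok = codes < 4
            self.n_skipped += int((~ok).sum())
            codes, quals, pos = codes[ok], quals[ok], pos[ok]
            np.add.at(self.counts[ref], (codes, pos), 1)
            np.add.at(self.qsum[ref], (codes, pos), quals.astype(float))
            np.add.at(self.lsum[ref], (codes, pos), _LOG1ME[quals])

    def _add_gapped(self, rec: AlignmentRecord) -> None:
        ref = rec.reference_id
        genome = self.genome[ref]
        i = 0  # read cursor
        j = rec.position
        for n, op in cigar_ops(rec.cigar):
            if op == "M":
                codes = CODE_OF[rec.seq[i : i + n]]
                quals = rec.qual[i : i + n].astype(np.int64)
                pos = np.arange(j, j + n)
                ok = codes < 4
                self.n_skipped += int((~ok).sum())
                np.add.at(self.counts[ref], (codes[ok], pos[ok]), 1)
                np.add.at(self.qsum[ref], (codes[ok], pos[ok]),
                          quals[ok].astype(float))
                np.add.at(self.lsum[ref], (codes[ok], pos[ok]),
                          _LOG1ME[quals[ok]])
                i += n
                j += n
            elif op == "I":
                if j > 0:
                    anchor = j - 1
                    ins = rec.seq[i : i + n].tobytes().decode()
                    rb = chr(genome[anchor])
                    key = (ref, anchor, rb, rb + ins)
                    self.indel_obs[key] = self.indel_obs.get(key, 0) + 1
                i += n
            elif op == "D":
                if j > 0:
                    anchor = j - 1
                    deleted = genome[anchor : j + n].tobytes().decode()
                    key = (ref, anchor, deleted, deleted[0])
                    self.indel_obs[key] = self.indel_obs.get(key, 0) + 1
                j += n
            else:
                raise ValueError(f"unsupported CIGAR op {op!r}")

    def column(self, ref: str, pos: int) -> PileupColumn | None:
        c = self.counts[ref][:, pos]
        if c.sum() == 0:
            return None
        bases = [chr(b) for b in BASES]
        return PileupColumn(
            reference_id=ref,
            position=pos,
            ref_base=chr(self.genome[ref][pos]),
            base_counts={b: int(c[i]) for i, b in enumerate(bases) if c[i]},
            base_qual_sums={
                b: float(self.qsum[ref][i, pos])
                for i, b in enumerate(bases) if c[i]
            },
            base_log1me_sums={
                b: float(self.lsum[ref][i, pos])
                for i, b in enumerate(bases) if c[i]
            },
        )

    def candidate_positions(self, ref: str) -> np.ndarray:
        """Sites carrying any non-reference base evidence."""
        counts = self.counts[ref]
        refcodes = CODE_OF[self.genome[ref]]
        depth = counts.sum(axis=0)
        covered = depth > 0
        ok = refcodes < 4
        refcount = np.zeros(len(refcodes), dtype=np.int64)
        idx = np.nonzero(ok)[0]
        refcount[idx] = counts[refcodes[idx], idx]
        return np.nonzero(covered & (depth > refcount))[0]


def compute_pileup(
    records: list[AlignmentRecord], genome: dict[str, np.ndarray]
) -> Pileup:
    pile = Pileup(genome)
    pile.add_records(records)
    return pile


def call_site(
    column: PileupColumn,
    min_alt_count: int = 2,
    max_qual: float = 1000.0,
) -> VariantCall | None:
    """Phred-scaled haploid site call; None when no alternate allele has
    the minimum read support."""
    ref = column.ref_base
    alts = [
        (n, b)
        for b, n in column.base_counts.items()
        if b != ref and n >= min_alt_count
    ]
    if not alts:
        return None
    alts.sort(key=lambda t: (-t[0], t[1]))

    genotypes = [chr(b) for b in BASES]
    ll = np.empty(4)
    for gi, g in enumerate(genotypes):
        total = 0.0
        for b, n in column.base_counts.items():
            if b == g:
                total += column.base_log1me_sums[b]
            else:
                total += -column.base_qual_sums[b] / 10.0 - n * LOG10_3
        ll[gi] = total
    m = ll.max()
    log_norm = m + np.log10(np.sum(10.0 ** (ll - m)))
    try:
        ref_idx = genotypes.index(ref)
        log_post_ref = ll[ref_idx] - log_norm
    except ValueError:  # reference base is N: no reference genotype
        log_post_ref = -max_qual / 10.0
    qual = float(min(max_qual, -10.0 * log_post_ref))
    return VariantCall(
        reference_id=column.reference_id,
        position=column.position,
        ref=ref,
        alts=[b for _n, b in alts],
        qual=max(qual, 0.0),
    )


def call_indels(
    pile: Pileup, min_support: int = 2, obs_phred: float = 30.0,
    max_qual: float = 1000.0,
) -> list[VariantCall]:
    """Indel calls from gapped alignments. The supporting gap observations
    are treated like alternate bases at a nominal Phred (heuristic: gap
    placement has no per-base quality), scored with the same posterior."""
    calls = []
    for (ref, pos, r, a), support in sorted(pile.indel_obs.items()):
        if support < min_support:
            continue
        depth = int(pile.counts[ref][:, pos].sum())
        other = max(depth - support, 0)
        e = 10.0 ** (-obs_phred / 10.0)
        ll_ref = other * np.log10(1 - e) + support * (-obs_phred / 10.0)
        ll_alt = support * np.log10(1 - e) + other * (-obs_phred / 10.0)
        m = max(ll_ref, ll_alt)
        log_norm = m + np.log10(10.0 ** (ll_ref - m) + 10.0 ** (ll_alt - m))
        qual = float(min(max_qual, -10.0 * (ll_ref - log_norm)))
        calls.append(VariantCall(ref, pos, r, [a], max(qual, 0.0)))
    return calls


def call_all_sites(
    pile: Pileup,
    min_alt_count: int = 2,
    with_indels: bool = True,
    snp_gap: int = 3,
) -> list[VariantCall]:
    """All substitution and indel calls over the pileup.

    Substitution calls within snp_gap bp of a supported indel are
    suppressed: reads whose tail crosses an indel score better with a
    terminal mismatch than with a gap, which would otherwise plant
    spurious substitution evidence at indel flanks (the usual
    indel-proximity filter of pileup callers)."""
    masked: dict[str, set[int]] = {}
    if snp_gap >= 0:
        for (ref, pos, r, _a), support in pile.indel_obs.items():
            if support < min_alt_count:
                continue
            span = len(r)
            masked.setdefault(ref, set()).update(
                range(pos - snp_gap, pos + span + snp_gap + 1)
            )
    calls: list[VariantCall] = []
    for ref in pile.genome:
        skip = masked.get(ref, ())
        for pos in pile.candidate_positions(ref):
            if int(pos) in skip:
                continue
            col = pile.column(ref, int(pos))
            c = call_site(col, min_alt_count=min_alt_count)
            if c is not None:
                calls.append(c)
    if with_indels:
        calls.extend(call_indels(pile, min_support=min_alt_count))
    calls.sort(key=lambda c: (c.reference_id, c.position, c.ref))
    return calls


def apply_corrections(
    genome: dict[str, np.ndarray],
    calls: list[VariantCall],
    qual_threshold: float = 5.0,
) -> tuple[dict[str, np.ndarray], int]:
    """Replace the reference base at every site whose call is strictly
    above the quality threshold and has exactly one alternate
    substitution allele. Everything else is left unapplied."""
    seen: set[tuple[str, int]] = set()
    for c in calls:
        key = (c.reference_id, c.position)
        if key in seen and c.is_substitution:
            raise ValueError(f"duplicate substitution call at {key}")
        if c.is_substitution:
            seen.add(key)
    corrected = {r: s.copy() for r, s in genome.items()}
    applied = 0
    for c in calls:
        if (
            c.qual > qual_threshold
            and c.n_alts == 1
            and c.is_substitution
        ):
            corrected[c.reference_id][c.position] = ord(c.alts[0])
            c.applied = True
            applied += 1
    return corrected, applied


def polish_iteratively(
    host_reference: dict[str, np.ndarray],
    reads: list[PairedRead],
    params: ScoreParams | None = None,
    n_iterations: int = 2,
    qual_threshold: float = 5.0,
    min_alt_count: int = 2,
    stop_when_converged: bool = False,
) -> tuple[dict[str, np.ndarray], PolishReport, list[list[VariantCall]]]:
    """The iterative correction loop: align -> pileup -> call -> apply,
    repeated (default twice); each iteration re-calls from scratch
    against the current genome."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    params = params or ScoreParams()
    genome = host_reference
    report = PolishReport()
    per_iter_calls: list[list[VariantCall]] = []
    for _it in range(n_iterations):
        index = KmerIndex(genome, params.seed_len)
        alns = align_pairs(reads, index, params)
        rate = mapping_rate(alns)
        recs = [r for pa in alns for r in pa.unique_records()]
        pile = compute_pileup(recs, genome)
        calls = call_all_sites(pile, min_alt_count=min_alt_count)
        detected = [c for c in calls if c.qual > qual_threshold]
        genome, applied = apply_corrections(genome, calls, qual_threshold)
        report.iterations.append(
            IterationStats(detected=len(detected), applied=applied,
                           mapping_rate=rate)
        )
        per_iter_calls.append(calls)
        if stop_when_converged and applied == 0:
            break
    return genome, report, per_iter_calls


def build_snp_index(
    corrected_genome: dict[str, np.ndarray],
    residual_calls: list[VariantCall],
    k: int = 20,
) -> SnpAwareIndex:
    """Final SNP-aware index: registers unapplied multi-allelic
    substitutions and indel calls as match-equivalent alleles."""
    subs: dict[str, dict[int, np.ndarray]] = {}
    indels: dict[str, list[Variant]] = {}
    n_multi = n_indel = 0
    for c in residual_calls:
        if c.applied:
            continue
        if c.is_substitution:
            if c.n_alts > 1:
                subs.setdefault(c.reference_id, {})[c.position] = np.frombuffer(
                    "".join(c.alts).encode(), dtype=np.uint8
                )
                n_multi += 1
        else:
            for alt in c.alts:
                indels.setdefault(c.reference_id, []).append(
                    Variant(c.position, c.ref, alt)
                )
                n_indel += 1
    idx = SnpAwareIndex(corrected_genome, subs, indels, k)
    idx.n_multi_alt = n_multi
    idx.n_indels = n_indel
    return idx


def polish_pipeline(
    host_reference: dict[str, np.ndarray],
    reads: list[PairedRead],
    params: ScoreParams | None = None,
    n_iterations: int = 2,
    qual_threshold: float = 5.0,
    min_alt_count: int = 2,
):
    """Full procedure: two correction iterations, a final call pass on the
    corrected genome, and a terminal SNP-aware index; stage mapping rates
    are reported for {raw, iter1, iter2, snp_aware}."""
    params = params or ScoreParams()
    genome, report, per_iter_calls = polish_iteratively(
        host_reference, reads, params, n_iterations, qual_threshold,
        min_alt_count,
    )
    # final pass on the corrected genome
    index = KmerIndex(genome, params.seed_len)
    alns = align_pairs(reads, index, params)
    rate_corrected = mapping_rate(alns)
    recs = [r for pa in alns for r in pa.unique_records()]
    pile = compute_pileup(recs, genome)
    residual = [
        c
        for c in call_all_sites(pile, min_alt_count=min_alt_count)
        if c.qual > qual_threshold
    ]
    snp_index = build_snp_index(genome, residual, params.seed_len)
    alns_aware = align_pairs(reads, snp_index, params)
    rate_aware = mapping_rate(alns_aware)

    stages = {"raw": report.iterations[0].mapping_rate}
    for i, it in enumerate(report.iterations[1:], start=1):
        stages[f"iter{i}"] = it.mapping_rate
    stages[f"iter{len(report.iterations)}"] = rate_corrected
    stages["snp_aware"] = rate_aware
    report.stage_mapping_rates = stages
    report.final_multi_alt_snps = snp_index.n_multi_alt
    report.final_indels = snp_index.n_indels
    return genome, report, residual, snp_index, per_iter_calls
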