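"""Seed-and-extend aligner: DP oracle equivalence, score threshold,
uniqueness and the SNP-aware matching contract."""

import numpy as np
import pytest

from dualseq.align import (
    KmerIndex,
    ScoreParams,
    SnpAwareIndex,
    align_read,
)
from dualseq.dp import (
    cigar_read_len,
    cigar_ref_len,
    fit_align,
    fit_score,
    substitution_scores,
)
from dualseq.sequences import BASES, revcomp, seq_to_array
from dualseq.variants import Variant

from oracles import brute_fit_score

PARAMS = ScoreParams(seed_len=8)
Q = lambda n: np.full(n, 40, dtype=np.uint8)


# --- DP engine ------------------------------------------------------------

def test_fit_dp_matches_brute_force_gotoh(rng):
    for _ in range(150):
        m = int(rng.integers(4, 25))
        n = int(rng.integers(m, 70))
        read = BASES[rng.integers(0, 4, m)]
        ref = BASES[rng.integers(0, 4, n)]
        S = substitution_scores(read, ref, 0, -6)
        assert fit_score(S, -5, -3) == brute_fit_score(read, ref, 0, -6, -5, -3)


def test_fit_traceback_consistent_with_score(rng):
    for _ in range(100):
        m = int(rng.integers(4, 25))
        n = int(rng.integers(m, 70))
        read = BASES[rng.integers(0, 4, m)]
        ref = BASES[rng.integers(0, 4, n)]
        S = substitution_scores(read, ref, 0, -6)
        score, start, end, cigar = fit_align(S, -5, -3)
        assert score == fit_score(S, -5, -3)
        assert cigar_read_len(cigar) == m
        assert start + cigar_ref_len(cigar) == end <= n


# --- k-mer index ----------------------------------------------------------

def test_index_lookup_enumerated_positions():
    genome = {"g": seq_to_array("ACGTACGTACGT")}
    idx = KmerIndex(genome, 8)
    hits = dict(idx.lookup(b"ACGTACGT"))
    assert sorted(hits["g"]) == [0, 4]
    assert dict(idx.lookup(b"TTTTTTTT")) == {}


def test_index_reverse_complement_symmetry(rng):
    seq = BASES[rng.integers(0, 4, 200)]
    fwd = KmerIndex({"g": seq}, 10)
    rev = KmerIndex({"g": revcomp(seq).copy()}, 10)
    for _ in range(20):
        i = int(rng.integers(0, 191))
        kmer = seq[i : i + 10]
        f = list(dict(fwd.lookup(kmer.tobytes())).get("g", []))
        r = list(dict(rev.lookup(revcomp(kmer).tobytes())).get("g", []))
        assert sorted(200 - 10 - p for p in r) == sorted(f) or (f == [] and r == [])


def test_short_sequence_warns_and_is_unplaceable():
    with pytest.warns(UserWarning, match="shorter than k"):
        idx = KmerIndex({"tiny": seq_to_array("ACGT")}, 8)
    assert dict(idx.lookup(b"ACGTACGT")) == {}


# --- read placement -------------------------------------------------------

def test_exact_substring_maps_with_zero_score(rng):
    ref = BASES[rng.integers(0, 4, 500)]
    idx = KmerIndex({"g": ref}, 8)
    read = ref[100:136].copy()
    rec = align_read(read, Q(36), idx, PARAMS)
    assert rec is not None
    assert rec.score == 0 >= PARAMS.min_score(36) == -22
    assert (rec.position, rec.strand, rec.cigar) == (100, "+", "36M")
    assert rec.is_unique


def test_read_below_threshold_is_unmapped(rng):
    ref = BASES[rng.integers(0, 4, 500)]
    idx = KmerIndex({"g": ref}, 8)
    read = ref[50:90].copy()
    # f(40) = -24: five mismatches (-30) sink it; DP oracle confirms
    for p in (8, 16, 22, 30, 38):
        read[p] = BASES[(int(np.argmax(BASES == read[p])) + 1) % 4]
    best = max(
        fit_score(substitution_scores(s, ref, 0, -6), -5, -3)
        for s in (read, revcomp(read))
    )
    assert best < PARAMS.min_score(40)
    assert align_read(read, Q(40), idx, PARAMS) is None


def test_duplicated_locus_flagged_non_unique(rng):
    core = BASES[rng.integers(0, 4, 60)]
    ref = np.concatenate([core, BASES[rng.integers(0, 4, 100)], core])
    idx = KmerIndex({"g": ref}, 8)
    read = core[10:50].copy()
    rec = align_read(read, Q(40), idx, PARAMS)
    assert rec is not None
    assert rec.mapping_count == 2
    assert not rec.is_unique


def test_reverse_strand_read_recovers_forward_locus(rng):
    ref = BASES[rng.integers(0, 4, 400)]
    idx = KmerIndex({"g": ref}, 8)
    read = revcomp(ref[200:250]).copy()
    rec = align_read(read, Q(50), idx, PARAMS)
    assert rec is not None
    assert (rec.position, rec.strand, rec.score) == (200, "-", 0)


def test_gapped_read_scores_and_cigar(rng):
    ref = BASES[rng.integers(0, 4, 400)]
    idx = KmerIndex({"g": ref}, 8)
    # delete 3 reference bases from the middle of a 60 bp read
    read = np.concatenate([ref[100:130], ref[133:163]]).copy()
    rec = align_read(read, Q(60), idx, PARAMS)
    assert rec is not None
    assert rec.score == -5 - 3 * 3  # one gap of length 3
    assert "D" in rec.cigar
    assert cigar_ref_len(rec.cigar) == 63


def test_tightening_score_threshold_never_increases_mapped_count(rng):
    # f(L) = A + B*L is a minimum score: raising B toward 0 raises the bar,
    # so the mapped set can only shrink
    ref = BASES[rng.integers(0, 4, 2000)]
    idx = KmerIndex({"g": ref}, 8)
    reads = []
    for _ in range(60):
        L = 50
        s = int(rng.integers(0, 1950))
        read = ref[s : s + L].copy()
        for p in rng.choice(L, size=int(rng.integers(0, 8)), replace=False):
            read[p] = BASES[(int(np.argmax(BASES == read[p])) + 1) % 4]
        reads.append(read)
    mapped_prev = None
    for slope in (-1.2, -0.8, -0.5, -0.3):
        params = ScoreParams(seed_len=8, threshold_slope=slope)
        mapped = sum(
            align_read(r, Q(len(r)), idx, params) is not None for r in reads
        )
        if mapped_prev is not None:
            assert mapped <= mapped_prev
        mapped_prev = mapped


# --- SNP-aware matching contract -----------------------------------------

def test_empty_variant_set_behaves_like_plain_index(rng):
    ref = BASES[rng.integers(0, 4, 600)]
    plain = KmerIndex({"g": ref}, 8)
    aware = SnpAwareIndex({"g": ref}, {}, {}, 8)
    for _ in range(25):
        s = int(rng.integers(0, 540))
        read = ref[s : s + 50].copy()
        for p in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
            read[p] = BASES[(int(np.argmax(BASES == read[p])) + 1) % 4]
        a = align_read(read, Q(50), plain, PARAMS)
        b = align_read(read, Q(50), aware, PARAMS)
        assert (a is None) == (b is None)
        if a is not None:
            assert (a.position, a.score, a.cigar) == (b.position, b.score, b.cigar)


def test_registered_alt_base_scores_as_match(rng):
    ref = BASES[rng.integers(0, 4, 600)]
    site = 220
    alt = BASES[(int(np.argmax(BASES == ref[site])) + 1) % 4]
    aware = SnpAwareIndex(
        {"g": ref}, {"g": {site: np.array([alt], dtype=np.uint8)}}, {}, 8
    )
    read_ref = ref[200:250].copy()
    read_alt = read_ref.copy()
    read_alt[20] = alt
    rec_ref = align_read(read_ref, Q(50), aware, PARAMS)
    rec_alt = align_read(read_alt, Q(50), aware, PARAMS)
    assert rec_ref.score == rec_alt.score == 0


def test_unregistered_mismatch_still_penalized(rng):
    ref = BASES[rng.integers(0, 4, 600)]
    aware = SnpAwareIndex({"g": ref}, {}, {}, 8)
    read = ref[300:350].copy()
    read[25] = BASES[(int(np.argmax(BASES == read[25])) + 1) % 4]
    rec = align_read(read, Q(50), aware, PARAMS)
    assert rec.score == PARAMS.mismatch_penalty


def test_registered_deletion_traversable_without_gap_penalty(rng):
    ref = BASES[rng.integers(0, 4, 600)]
    # the sequenced strain lacks ref[301:304]
    v = Variant(300, ref[300:304].tobytes().decode(), chr(ref[300]))
    aware = SnpAwareIndex({"g": ref}, {}, {"g": [v]}, 8)
    plain = KmerIndex({"g": ref}, 8)
    read = np.concatenate([ref[270:301], ref[304:333]]).copy()
    rec_plain = align_read(read, Q(60), plain, PARAMS)
    rec_aware = align_read(read, Q(60), aware, PARAMS)
    assert rec_plain.score == -5 - 3 * 3  # pays the gap on the plain index
    assert rec_aware.score == 0           # traverses the registered indel free
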