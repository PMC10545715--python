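"""Pileup, Phred-scaled site calling, conditional correction and the
iterative polish loop."""

import numpy as np
import pytest

from dualseq.align import (
    AlignmentRecord,
    KmerIndex,
    ScoreParams,
    pairs_from_batch,
)
from dualseq.polish import (
    LOG10_3,
    PileupColumn,
    VariantCall,
    apply_corrections,
    build_snp_index,
    call_site,
    compute_pileup,
    polish_iteratively,
)
from dualseq.sequences import seq_to_array
from dualseq.simulate import simulate_genomes, simulate_reads
from dualseq.vcfio import read_vcf, write_vcf


def rec(seq, pos, read_id="r", qual=30, cigar=None):
    arr = seq_to_array(seq)
    return AlignmentRecord(
        read_id=read_id, mate=1, reference_id="g", position=pos, strand="+",
        cigar=cigar or f"{len(arr)}M", score=0, is_unique=True,
        mapping_count=1, seq=arr,
        qual=np.full(len(arr), qual, dtype=np.uint8),
    )


@pytest.fixture
def genome():
    return {"g": seq_to_array("ACGTACGTACGTACGTACGT")}


# --- pileup ---------------------------------------------------------------

def test_pileup_counts_reference_bases(genome):
    pile = compute_pileup([rec("ACGTA", 0, f"r{i}") for i in range(5)], genome)
    col = pile.column("g", 2)
    assert col.base_counts == {"G": 5}
    assert col.depth == 5


def test_pileup_stacks_mixed_evidence(genome):
    records = [rec("ACGTA", 0, f"ref{i}") for i in range(3)]
    records += [rec("ACTTA", 0, f"alt{i}") for i in range(2)]  # G->T at pos 2
    pile = compute_pileup(records, genome)
    col = pile.column("g", 2)
    assert col.base_counts == {"G": 3, "T": 2}


def test_uncovered_site_yields_no_column(genome):
    pile = compute_pileup([rec("ACGTA", 0)], genome)
    assert pile.column("g", 10) is None


def test_unknown_reference_is_a_hard_error(genome):
    bad = rec("ACGTA", 0)
    bad.reference_id = "nope"
    with pytest.raises(KeyError, match="unknown sequence"):
        compute_pileup([bad], genome)


def test_gapped_read_projects_through_cigar(genome):
    # read ACGTGTACGT = ref[0:4] + (deletion of ref[4:6]) wait: craft
    # explicitly: 4M2D4M consumes ref ACGT--CGTA reading ACGT then CGTA
    r = rec("ACGTCGTA", 0, cigar="4M2D4M")
    pile = compute_pileup([r], genome)
    assert pile.column("g", 3).base_counts == {"T": 1}
    assert pile.column("g", 4) is None        # deleted column: no base
    assert pile.column("g", 6).base_counts == {"C": 1}
    assert ("g", 3, "TAC", "T") in pile.indel_obs  # anchored deletion record


# --- site calling ---------------------------------------------------------

def column(ref_base, bases, qual=30):
    counts, qsums, lsums = {}, {}, {}
    e = 10 ** (-qual / 10)
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
        qsums[b] = qsums.get(b, 0.0) + qual
        lsums[b] = lsums.get(b, 0.0) + np.log10(1 - e)
    return PileupColumn("g", 0, ref_base, counts, qsums, lsums)


def test_unanimous_alternate_is_called_with_high_quality():
    col = column("A", "C" * 10, qual=30)
    call = call_site(col)
    assert call is not None and call.alts == ["C"] and call.n_alts == 1
    # closed form: P(ref | data) ~ (e/3)^10 / (1-e)^10 -> QUAL >> 5
    assert call.qual > 300


def test_all_reference_column_yields_no_call():
    assert call_site(column("A", "A" * 8)) is None


def test_two_alternate_alleles_counted():
    call = call_site(column("A", "C" * 5 + "G" * 5))
    assert call.n_alts == 2
    assert set(call.alts) == {"C", "G"}


def test_single_observation_qual_matches_closed_form():
    # one alt read at Phred Q: P(ref|data) = e/3 exactly (flat prior),
    # so QUAL = Q + 10*log10(3)
    for q in (10, 20, 30):
        col = column("A", "C", qual=q)
        call = call_site(col, min_alt_count=1)
        assert call.qual == pytest.approx(q + 10 * LOG10_3, abs=1e-6)


def test_lone_read_below_support_threshold_is_not_called():
    assert call_site(column("A", "C"), min_alt_count=2) is None


# --- corrections ----------------------------------------------------------

def test_correction_threshold_is_strict(genome):
    just_above = VariantCall("g", 0, "A", ["G"], qual=5.1)
    exactly_at = VariantCall("g", 4, "A", ["G"], qual=5.0)
    multi = VariantCall("g", 8, "A", ["C", "G"], qual=40.0)
    corrected, applied = apply_corrections(
        genome, [just_above, exactly_at, multi], qual_threshold=5.0
    )
    assert applied == 1
    assert just_above.applied and not exactly_at.applied and not multi.applied
    assert chr(corrected["g"][0]) == "G"
    assert chr(corrected["g"][4]) == "A"
    assert len(corrected["g"]) == len(genome["g"])  # substitutions only


def test_duplicate_calls_at_one_site_rejected(genome):
    calls = [
        VariantCall("g", 3, "T", ["A"], 30.0),
        VariantCall("g", 3, "T", ["C"], 30.0),
    ]
    with pytest.raises(ValueError, match="duplicate"):
        apply_corrections(genome, calls)


def test_indel_calls_are_never_applied(genome):
    indel = VariantCall("g", 2, "GT", ["G"], qual=60.0)
    corrected, applied = apply_corrections(genome, [indel])
    assert applied == 0
    assert np.array_equal(corrected["g"], genome["g"])


# --- the iterative loop ---------------------------------------------------

def test_zero_divergence_polish_is_idempotent(clean_cfg):
    genomes, truth = simulate_genomes(clean_cfg)
    pairs = pairs_from_batch(simulate_reads(genomes, truth, clean_cfg)[("0h", 1)])
    corrected, report, _calls = polish_iteratively(
        genomes.host_reference, pairs, ScoreParams(), n_iterations=2
    )
    assert [it.applied for it in report.iterations] == [0, 0]
    assert np.array_equal(corrected["host_1"], genomes.host_reference["host_1"])


def test_polish_requires_at_least_one_iteration(clean_cfg):
    genomes, truth = simulate_genomes(clean_cfg)
    pairs = pairs_from_batch(simulate_reads(genomes, truth, clean_cfg)[("0h", 1)])
    with pytest.raises(ValueError):
        polish_iteratively(genomes.host_reference, pairs, n_iterations=0)


def test_snp_index_registers_only_unapplied_variants(genome):
    applied = VariantCall("g", 0, "A", ["G"], 30.0, applied=True)
    multi = VariantCall("g", 4, "A", ["C", "G"], 30.0)
    indel = VariantCall("g", 8, "AC", ["A"], 30.0)
    idx = build_snp_index(genome, [applied, multi, indel], k=8)
    assert idx.n_multi_alt == 1 and idx.n_indels == 1
    assert 4 in idx.substitutions["g"] and 0 not in idx.substitutions.get("g", {})


# --- VCF round trip -------------------------------------------------------

def test_vcf_positions_are_one_based_and_multiallelic_rows_joined(tmp_path):
    calls = [
        VariantCall("g", 0, "A", ["G"], 12.5),
        VariantCall("g", 9, "A", ["C", "G"], 44.0),
    ]
    path = tmp_path / "x.vcf"
    write_vcf(calls, {"g": 20}, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert lines[0].split("\t")[1] == "1"
    assert lines[1].split("\t")[4] == "C,G"


def test_vcf_round_trip_of_random_calls(tmp_path, rng):
    calls = []
    taken = set()
    for _ in range(50):
        pos = int(rng.integers(0, 10_000))
        if pos in taken:
            continue
        taken.add(pos)
        ref = "ACGT"[int(rng.integers(4))]
        alts = sorted({"ACGT"[int(rng.integers(4))] for _ in range(
            int(rng.integers(1, 3)))} - {ref})
        if not alts:
            continue
        calls.append(
            VariantCall("g", pos, ref, alts, float(rng.uniform(0, 100)),
                        applied=bool(rng.integers(2)))
        )
    calls.sort(key=lambda c: c.position)
    path = tmp_path / "rt.vcf"
    write_vcf(calls, {"g": 10_000}, path)
    back = read_vcf(path)
    assert len(back) == len(calls)
    for a, b in zip(calls, back):
        assert (a.reference_id, a.position, a.ref, a.alts, a.applied) == (
            b.reference_id, b.position, b.ref, b.alts, b.applied
        )
        assert b.qual == pytest.approx(a.qual, rel=1e-5)


def test_vcf_rejects_unsorted_calls(tmp_path):
    calls = [VariantCall("g", 5, "A", ["C"], 10.0),
             VariantCall("g", 1, "A", ["C"], 10.0)]
    with pytest.raises(ValueError, match="sorted"):
        write_vcf(calls, {"g": 10}, tmp_path / "bad.vcf")


def test_vcf_readable_by_independent_parser(tmp_path):
    cyvcf2 = pytest.importorskip("cyvcf2")
    calls = [VariantCall("g", 2, "A", ["C", "T"], 33.25)]
    path = tmp_path / "c.vcf"
    write_vcf(calls, {"g": 20}, path)
    var = next(iter(cyvcf2.VCF(str(path))))
    assert var.POS == 3 and var.REF == "A" and var.ALT == ["C", "T"]
    assert var.QUAL == pytest.approx(33.25)
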