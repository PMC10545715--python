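"""Fragment counting, FPKM arithmetic, replicate pooling and presence-set
algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualseq.align import (
    AlignmentRecord,
    KmerIndex,
    PairAlignment,
    ScoreParams,
    align_pairs,
    pairs_from_batch,
)
from dualseq.genes import GeneModel
from dualseq.quantify import (
    count_fragments,
    fpkm,
    organism_fractions,
    pool_replicates,
    presence_sets,
    top_expressed,
)
from dualseq.simulate import simulate_genomes, simulate_reads

from oracles import brute_venn_regions

GENES = [
    GeneModel("gA", "c", 0, 1000, "+"),
    GeneModel("gB", "c", 1000, 2500, "-"),
]


def pair_at(rid, start, end):
    def r(pos, length, mate):
        return AlignmentRecord(
            read_id=rid, mate=mate, reference_id="c", position=pos,
            strand="+", cigar=f"{length}M", score=0, is_unique=True,
            mapping_count=1, seq=np.zeros(length, np.uint8),
            qual=np.zeros(length, np.uint8),
        )
    return PairAlignment(rid, r(start, 100, 1), r(end - 100, 100, 2))


def test_fragment_assigned_by_span_midpoint():
    counts, total = count_fragments([pair_at("f1", 100, 600)], GENES)
    assert counts["gA"] == 1 and counts["gB"] == 0 and total == 1


def test_intergenic_fragment_counts_toward_total_only():
    counts, total = count_fragments([pair_at("f1", 2400, 2900)], GENES)
    # span [2400, 2900): midpoint 2650 beyond the last gene end
    assert counts.sum() == 0 and total == 1


def test_simulated_fragment_counts_equal_truth_tally(clean_cfg):
    genomes, truth = simulate_genomes(clean_cfg)
    batch = simulate_reads(genomes, truth, clean_cfg)[("0h", 1)]
    pairs = pairs_from_batch(batch)
    index = KmerIndex(genomes.host_strain, 20)
    alns = align_pairs(pairs, index, ScoreParams())
    counts, total = count_fragments(alns, truth.host_genes())
    tally = {}
    for rid in batch.ids:
        tally[truth.read_origins[rid].gene_id] = (
            tally.get(truth.read_origins[rid].gene_id, 0) + 1
        )
    assert total == batch.n_pairs
    # fragments are sampled wholly inside their source gene, so the
    # midpoint rule must reproduce the truth tally exactly
    for gid, n in tally.items():
        assert counts[gid] == n


@pytest.mark.parametrize(
    "count,length,total,expected",
    [
        (10, 1000, 10**6, 10.0),
        (0, 1000, 10**6, 0.0),
        (7, 2500, 2 * 10**5, 14.0),
    ],
)
def test_fpkm_hand_arithmetic(count, length, total, expected):
    counts = pd.Series({"g": count})
    lengths = pd.Series({"g": length})
    assert fpkm(counts, lengths, total)["g"] == pytest.approx(expected, abs=1e-12)


def test_fpkm_rejects_empty_sample():
    with pytest.raises(ValueError, match="positive"):
        fpkm(pd.Series({"g": 0}), pd.Series({"g": 100}), 0)


def test_fpkm_scale_invariance(rng):
    counts = pd.Series(rng.integers(0, 50, 30).astype(int))
    lengths = pd.Series(rng.integers(200, 2000, 30).astype(int))
    total = int(counts.sum() + 1000)
    a = fpkm(counts, lengths, total)
    b = fpkm(2 * counts, lengths, 2 * total)
    pd.testing.assert_series_equal(a, b)


def test_fpkm_conservation_identity(rng):
    counts = pd.Series(rng.integers(0, 100, 50).astype(int))
    lengths = pd.Series(rng.integers(100, 3000, 50).astype(int))
    total = int(counts.sum()) + 500
    vals = fpkm(counts, lengths, total)
    lhs = float((vals * lengths / 1e3).sum())
    rhs = 1e6 * counts.sum() / total
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_pooling_sums_counts_and_totals():
    r = {
        "a": (pd.Series({"g1": 3, "g2": 0}), 10),
        "b": (pd.Series({"g1": 4, "g2": 2}), 20),
        "c": (pd.Series({"g1": 5, "g2": 1}), 30),
    }
    pooled = pool_replicates(r, {"a": "t1", "b": "t1", "c": "t2"})
    assert pooled["t1"][0]["g1"] == 7 and pooled["t1"][1] == 30
    assert pooled["t2"][0]["g1"] == 5 and pooled["t2"][1] == 30


def test_pooling_single_replicate_is_identity():
    r = {"a": (pd.Series({"g": 3}), 10)}
    pooled = pool_replicates(r, {"a": "t"})
    assert pooled["t"][0].equals(r["a"][0]) and pooled["t"][1] == 10


def test_pooling_rejects_mismatched_gene_universes():
    r = {
        "a": (pd.Series({"g1": 1}), 5),
        "b": (pd.Series({"g2": 1}), 5),
    }
    with pytest.raises(ValueError, match="universes"):
        pool_replicates(r, {"a": "t", "b": "t"})


def test_presence_regions_match_exhaustive_enumeration(rng):
    for _ in range(20):
        mat = pd.DataFrame(
            rng.random((20, 4)) * (rng.random((20, 4)) > 0.35),
            index=[f"g{i}" for i in range(20)],
            columns=list("WXYZ"),
        )
        ps = presence_sets(mat)
        assert ps.region_counts == brute_venn_regions(ps.sets)
        # the 15 exclusive regions partition the union
        assert sum(ps.region_counts.values()) == ps.union_size


def test_presence_membership_edges():
    mat = pd.DataFrame(
        {"t1": [1.0, 0.0], "t2": [2.0, 0.0], "t3": [3.0, 0.0], "t4": [4.0, 5.0]},
        index=["everywhere", "late_only"],
    )
    ps = presence_sets(mat)
    assert ps.region_counts[frozenset(["t1", "t2", "t3", "t4"])] == 1
    assert ps.specific_counts["t4"] == 1
    assert ps.percentages["t4"] == 100.0


def test_organism_fraction_arithmetic():
    class Fake:
        def __init__(self, p, h, u=0):
            self.pathogen_alignments = [None] * p
            self.host_alignments = [None] * h
            self.unmapped_ids = set(range(u))

    pooled = organism_fractions(
        {"s1": Fake(10, 90), "s2": Fake(0, 50)},
        {"s1": "3h", "s2": "12h"},
    )
    assert pooled.loc["3h", "pathogen_fraction"] == pytest.approx(0.10)
    assert pooled.loc["12h", "pathogen_fraction"] == 0.0


def test_top_expressed_ordering_and_tie_break():
    mat = pd.DataFrame(
        {"s": [5.0, 9.0, 5.0, 1.0]}, index=["gb", "gd", "ga", "gc"]
    )
    top = top_expressed(mat, "s", n=3)
    assert list(top["gene_id"]) == ["gd", "ga", "gb"]  # tie 5.0: ga before gb
    with pytest.warns(UserWarning, match="returning all"):
        assert len(top_expressed(mat, "s", n=10)) == 4


def test_planted_high_expression_gene_ranks_first(small_world):
    cfg, genomes, truth, batches = small_world
    pairs = pairs_from_batch(batches[("0h", 1)])
    index = KmerIndex(genomes.pathogen, 20)
    alns = [pa for pa in align_pairs(pairs, index, ScoreParams()) if pa.is_mapped]
    genes = truth.pathogen_genes()
    counts, total = count_fragments(alns, genes)
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    mat = pd.DataFrame({"pooled": fpkm(counts, lengths, total)})
    top = top_expressed(mat, "pooled", n=1)
    assert top["gene_id"].iloc[0] == truth.boosted_gene


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_presence_partition_property(seed):
    r = np.random.default_rng(seed)
    mat = pd.DataFrame(r.random((12, 4)) * (r.random((12, 4)) > 0.5))
    ps = presence_sets(mat)
    assert sum(ps.region_counts.values()) == ps.union_size
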