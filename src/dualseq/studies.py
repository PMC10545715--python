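"""Canned study scenarios: the fixed experimental conditions under which
the pipeline's parameter-recovery properties are evaluated.

Each function builds its inputs with the synthetic-data generator at the
stated condition, runs the relevant pipeline stage(s), and returns plain
dictionaries of measured quantities. The conditions (genome sizes,
divergence, coverage, read counts, cluster geometry) are the study
design, not tunables; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import (
    KmerIndex,
    ScoreParams,
    align_read,
    pairs_from_batch,
)
from .coexpress import select_cluster_count, upgma
from .config import QualityModel, SimulationConfig
from .dp import fit_score, substitution_scores
from .partition import partition_reads
from .polish import polish_pipeline
from .quantify import count_fragments, fpkm, pool_replicates
from .sequences import BASES, revcomp
from .simulate import (
    simulate_genomes,
    simulate_profile_matrix,
    simulate_reads,
)


def polish_conditions(seed: int, base_error_rate: float = 0.0) -> SimulationConfig:
    """100 kb host at 0.5% substitution divergence, 30x 2x100 bp coverage
    (15,000 pairs), flat expression so coverage is uniform across genes."""
    return SimulationConfig(
        seed=seed,
        timepoints=("0h",),
        pathogen_read_fraction=(0.0,),
        replicates_per_timepoint=1,
        reads_per_sample=15_000,
        base_error_rate=base_error_rate,
        quality_model=QualityModel(tail_prob=0.0),
        abundance_sigma=0.0,
        cluster_profile_amplitude=0.0,
    )


def polish_study(seed: int, base_error_rate: float = 0.0) -> dict:
    """Run the full correction pipeline and score it against the truth:
    fraction of injected substitutions corrected, false-correction rate,
    per-iteration detected-SNP counts and stage mapping rates."""
    cfg = polish_conditions(seed, base_error_rate)
    genomes, truth = simulate_genomes(cfg)
    pairs = pairs_from_batch(simulate_reads(genomes, truth, cfg)[("0h", 1)])
    corrected, report, _residual, _index, per_iter = polish_pipeline(
        genomes.host_reference, pairs
    )
    ref_id = next(iter(corrected))
    true_snp = {v.pos: v.alt for v in truth.true_variants if v.is_snp}
    recovered = sum(
        1 for p, a in true_snp.items() if chr(corrected[ref_id][p]) == a
    )
    applied = [c.position for calls in per_iter for c in calls if c.applied]
    false = [p for p in applied if p not in true_snp]
    rates = report.stage_mapping_rates
    return dict(
        n_true_snps=len(true_snp),
        recovered=recovered,
        recovery_fraction=recovered / len(true_snp),
        n_applied=len(applied),
        n_false=len(false),
        false_fraction=len(false) / max(len(applied), 1),
        detected_per_iteration=[it.detected for it in report.iterations],
        stage_mapping_rates=rates,
        genome_length_conserved=(
            len(corrected[ref_id])
            == len(genomes.host_reference[ref_id])
        ),
    )


def partition_conditions(
    seed: int, n_host_pairs: int = 25_000, n_pathogen_pairs: int = 250
) -> SimulationConfig:
    frac = n_pathogen_pairs / (n_host_pairs + n_pathogen_pairs)
    return SimulationConfig(
        seed=seed,
        timepoints=("0h",),
        pathogen_read_fraction=(frac,),
        replicates_per_timepoint=1,
        reads_per_sample=n_host_pairs + n_pathogen_pairs,
    )


def partition_study(seed: int) -> dict:
    """Two independent random genomes, ~50,000 host + ~500 pathogen reads:
    sequential partition purity, host contamination of the pathogen
    partition, cross-mapping diagnostic, disjoint-cover check."""
    from .trim import trim_batch

    cfg = partition_conditions(seed)
    genomes, truth = simulate_genomes(cfg)
    batch = simulate_reads(genomes, truth, cfg)[("0h", 1)]
    trimmed, _ = trim_batch(batch)
    pairs = pairs_from_batch(trimmed)
    params = ScoreParams()
    result = partition_reads(
        pairs,
        KmerIndex(genomes.pathogen, params.seed_len),
        KmerIndex(genomes.host_reference, params.seed_len),
        params,
    )
    all_ids = {p.read_id for p in pairs}
    path_ids = {pa.read_id for pa in result.pathogen_alignments}
    host_ids = {pa.read_id for pa in result.host_alignments}
    true_path = {
        rid
        for rid, o in truth.read_origins.items()
        if o.organism == "pathogen" and rid in all_ids
    }
    disjoint = (
        path_ids | host_ids | result.unmapped_ids == all_ids
        and not (path_ids & host_ids)
        and not (path_ids & result.unmapped_ids)
        and not (host_ids & result.unmapped_ids)
    )
    return dict(
        n_pairs=len(all_ids),
        n_pathogen_origin=len(true_path),
        purity=len(path_ids & true_path) / max(len(true_path), 1),
        contamination=len(path_ids - true_path) / max(len(path_ids), 1),
        cross_mapped=result.cross_mapped,
        disjoint_cover=disjoint,
        fractions=result.per_organism_fractions,
    )


def aligner_oracle_study(
    seed: int, n_reads: int = 200, ref_len: int = 2000
) -> dict:
    """Seeded aligner vs exhaustive affine-gap DP over all positions and
    strands, on mutated substrings (<= 2 substitutions plus at most one
    indel of <= 5 bp, so at least one seed survives by pigeonhole)."""
    rng = np.random.default_rng([seed, 41])
    ref = BASES[rng.integers(0, 4, ref_len)]
    genome = {"ref": ref}
    params = ScoreParams(seed_len=10)
    index = KmerIndex(genome, params.seed_len)

    agree = 0
    for _ in range(n_reads):
        L = int(rng.integers(40, 61))
        start = int(rng.integers(0, ref_len - L - 1))
        read = ref[start : start + L].copy()
        if rng.random() < 0.5:
            read = revcomp(read).copy()
        read = read.tolist()
        for _s in range(int(rng.integers(0, 3))):
            p = int(rng.integers(0, len(read)))
            old = int(np.argmax(BASES == read[p]))
            read[p] = int(BASES[(old + int(rng.integers(1, 4))) % 4])
        if rng.random() < 0.5:
            p = int(rng.integers(1, len(read) - 1))
            ilen = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                read[p:p] = [int(b) for b in BASES[rng.integers(0, 4, ilen)]]
            else:
                del read[p : p + ilen]
        read = np.array(read, dtype=np.uint8)

        exhaustive = max(
            fit_score(
                substitution_scores(s, ref, params.match,
                                    params.mismatch_penalty),
                params.gap_open,
                params.gap_extend,
            )
            for s in (read, revcomp(read))
        )
        rec = align_read(
            read, np.full(len(read), 40, np.uint8), index, params
        )
        thr = params.min_score(len(read))
        if rec is None:
            agree += exhaustive < thr
        else:
            agree += rec.score == exhaustive
    return dict(n_reads=n_reads, agreement=agree / n_reads)


def cluster_recovery_study(
    seed: int, n_runs: int = 20, n_genes: int = 500, k_true: int = 8
) -> dict:
    """Davies-Bouldin selection of the planted cluster count over seeded
    replicates (500 genes, 4 timepoints, centroid separation 10x the
    within-cluster SD)."""
    wins = 0
    for r in range(n_runs):
        df, _labels, _cent = simulate_profile_matrix(
            n_genes, 4, k_true, noise_sd=0.2, separation=10.0,
            seed=int(np.random.default_rng([seed, 51, r]).integers(2**31)),
        )
        dend = upgma(df)
        sel = select_cluster_count(dend, df, 2, n_genes // 2)
        wins += sel.chosen_k == k_true
    return dict(n_runs=n_runs, recovered_runs=wins, k_true=k_true)


def fpkm_conservation_study(seed: int) -> dict:
    """FPKM bookkeeping on a simulated sample: the length-weighted FPKM
    sum must equal 1e6 * assigned/total, and pooled-replicate FPKM must
    equal FPKM of the merged alignment set."""
    cfg = SimulationConfig(
        seed=seed,
        timepoints=("0h",),
        pathogen_read_fraction=(0.0,),
        replicates_per_timepoint=2,
        reads_per_sample=2_000,
    )
    genomes, truth = simulate_genomes(cfg)
    batches = simulate_reads(genomes, truth, cfg)
    genes = truth.host_genes()
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    params = ScoreParams()
    index = KmerIndex(genomes.host_strain, params.seed_len)

    per_rep = {}
    all_alns = []
    from .align import align_pairs

    for rep in (1, 2):
        alns = align_pairs(pairs_from_batch(batches[("0h", rep)]), index, params)
        all_alns.extend(alns)
        per_rep[f"r{rep}"] = count_fragments(alns, genes)

    conservation_err = 0.0
    for counts, total in per_rep.values():
        vals = fpkm(counts, lengths, total)
        lhs = float((vals * lengths / 1e3).sum())
        rhs = 1e6 * counts.sum() / total
        conservation_err = max(conservation_err, abs(lhs - rhs))

    pooled = pool_replicates(per_rep, {"r1": "0h", "r2": "0h"})
    pc, pt = pooled["0h"]
    merged_counts, merged_total = count_fragments(all_alns, genes)
    pooled_fpkm = fpkm(pc, lengths, pt)
    merged_fpkm = fpkm(merged_counts, lengths, merged_total)
    pool_err = float((pooled_fpkm - merged_fpkm).abs().max())
    return dict(
        conservation_max_abs_err=conservation_err,
        pooling_max_abs_err=pool_err,
    )


def venn_study(seed: int, n_trials: int = 50, n_genes: int = 20) -> dict:
    """Presence-set Venn regions vs exhaustive per-element enumeration on
    random 20-gene x 4-timepoint matrices."""
    from .quantify import presence_sets

    rng = np.random.default_rng([seed, 61])
    tps = ["3h", "12h", "48h", "72h"]
    agree = 0
    for _ in range(n_trials):
        mat = pd.DataFrame(
            rng.random((n_genes, 4)) * (rng.random((n_genes, 4)) > 0.4),
            index=[f"g{i}" for i in range(n_genes)],
            columns=tps,
        )
        ps = presence_sets(mat, threshold=0.0)
        # exhaustive: scan every gene's membership signature
        brute: dict[frozenset, int] = {k: 0 for k in ps.region_counts}
        for gene in mat.index:
            sig = frozenset(t for t in tps if mat.at[gene, t] > 0.0)
            if sig:
                brute[sig] += 1
        agree += brute == ps.region_counts
    return dict(n_trials=n_trials, agreement=agree / n_trials)
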