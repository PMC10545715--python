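"""Synthetic dual RNA-seq data with recorded ground truth.

Generates (a) a pathogen reference, a host reference and a divergent host
*strain* genome (the insects sequenced are never the strain of the
assembly), (b) per-sample paired-end reads drawn from both organisms at a
configured, strongly unequal mixing fraction, with expression-weighted
sampling over planted temporal co-expression clusters, and (c) a TruthSet
recording every variant, read origin and cluster label so downstream
stages can be scored by parameter recovery rather than by eye.

Randomness is organised in named child streams of the config seed:
  default_rng([seed, 101])          variant COUNT draws (binomial, in order
                                    n_snps then n_indels)
  default_rng([seed, 102])          genome composition, gene tiling,
                                    variant placement, expression program
  default_rng([seed, 201, ti, ri])  reads of sample (timepoint ti, rep ri)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genes import GeneModel, tile_genes
from .sequences import (
    BASES,
    CODE_OF,
    error_to_phred,
    random_genome,
    revcomp,
)
from .variants import CoordinateLift, Variant, apply_variants

HOST_REF_ID = "host_1"
PATHOGEN_REF_ID = "pathogen_1"

_COUNT_STREAM = 101
_GENOME_STREAM = 102
_READ_STREAM = 201


@dataclass
class GenomeSet:
    pathogen: dict[str, np.ndarray]
    host_reference: dict[str, np.ndarray]
    host_strain: dict[str, np.ndarray]


@dataclass(frozen=True)
class ReadOrigin:
    organism: str  # "host" | "pathogen"
    gene_id: str
    fragment_start: int  # on the source genome (host strain / pathogen)
    sample: str


@dataclass
class TruthSet:
    true_variants: list[Variant]
    gene_models: list[GeneModel]
    true_cluster_labels: dict[str, int]
    true_profiles: np.ndarray  # clusters x timepoints, log2 scale
    gene_abundance: dict[str, float]
    boosted_gene: str
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def host_genes(self) -> list[GeneModel]:
        return [g for g in self.gene_models if g.reference_id == HOST_REF_ID]

    def pathogen_genes(self) -> list[GeneModel]:
        return [g for g in self.gene_models if g.reference_id == PATHOGEN_REF_ID]


@dataclass
class ReadBatch:
    """One library: paired mates held as right-aligned uint8 matrices."""

    sample: str
    timepoint: str
    replicate: int
    ids: list[str]
    seq1: np.ndarray
    qual1: np.ndarray  # Phred values (not ASCII)
    seq2: np.ndarray
    qual2: np.ndarray
    len1: np.ndarray
    len2: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.ids)

    def mate(self, which: int):
        if which == 1:
            return self.seq1, self.qual1, self.len1
        return self.seq2, self.qual2, self.len2


# ---------------------------------------------------------------------------
# genomes, variants and the expression program
# ---------------------------------------------------------------------------

def _place_variants(
    cfg: SimulationConfig,
    host: np.ndarray,
    n_snps: int,
    n_indels: int,
    rng: np.random.Generator,
) -> list[Variant]:
    L = len(host)
    occupied = np.zeros(L, dtype=bool)

    def claim(start: int, span: int, buffer: int = 1) -> bool:
        lo = max(0, start - buffer)
        hi = min(L, start + span + buffer)
        if occupied[lo:hi].any():
            return False
        occupied[lo:hi] = True
        return True

    snp_positions: list[int] = []

    # Hotspots: dense runs of substitutions (overdispersed divergence).
    n_hot_total = int(round(cfg.snp_hotspot_fraction * n_snps))
    n_spots = cfg.n_snp_hotspots if n_hot_total > 0 else 0
    if n_spots > 0:
        per_spot = np.full(n_spots, n_hot_total // n_spots)
        per_spot[: n_hot_total % n_spots] += 1
        margin = 2000
        for count in per_spot:
            if count < 1:
                continue
            width = max(int(np.ceil(count / cfg.snp_hotspot_density)), int(count))
            for _ in range(1000):  # deterministic rejection sampling
                start = int(rng.integers(margin, max(margin + 1, L - width - margin)))
                if not occupied[max(0, start - 500) : start + width + 500].any():
                    break
            offs = rng.choice(width, size=int(count), replace=False)
            for o in np.sort(offs):
                p = start + int(o)
                if claim(p, 1, buffer=0):
                    snp_positions.append(p)

    # Remaining substitutions uniform over the genome.
    need = n_snps - len(snp_positions)
    while need > 0:
        cands = rng.integers(0, L, size=max(2 * need, 16))
        for p in cands:
            if need == 0:
                break
            if claim(int(p), 1, buffer=0):
                snp_positions.append(int(p))
                need -= 1

    variants: list[Variant] = []
    for p in snp_positions:
        ref = chr(host[p])
        choices = [b for b in "ACGT" if b != ref]
        variants.append(Variant(p, ref, choices[int(rng.integers(3))]))

    # Indels: drawn length 1..indel_max_len, 50/50 insertion/deletion,
    # kept clear of substitutions and of each other.
    placed = 0
    while placed < n_indels:
        p = int(rng.integers(1, L - cfg.indel_max_len - 2))
        length = int(rng.integers(1, cfg.indel_max_len + 1))
        if rng.random() < 0.5:  # insertion after the anchor base
            if not claim(p, 1, buffer=2):
                continue
            ins = "".join(chr(b) for b in BASES[rng.integers(0, 4, size=length)])
            variants.append(Variant(p, chr(host[p]), chr(host[p]) + ins))
        else:  # deletion of `length` bases after the anchor
            if not claim(p, 1 + length, buffer=2):
                continue
            ref = "".join(chr(b) for b in host[p : p + 1 + length])
            variants.append(Variant(p, ref, ref[0]))
        placed += 1

    return sorted(variants)


def _cluster_centroids(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """K x T log2 centroids with pairwise separation >= separation * noise SD."""
    K, T = cfg.n_clusters, len(cfg.timepoints)
    if K == 1 or T < 2 or cfg.cluster_profile_amplitude == 0:
        # separation is only meaningful for a multi-timepoint profile
        return rng.normal(0.0, cfg.cluster_profile_amplitude, size=(K, T))
    min_d = cfg.cluster_min_separation * cfg.cluster_profile_sd
    amp = cfg.cluster_profile_amplitude
    for attempt in range(500):
        cent = rng.normal(0.0, amp, size=(K, T))
        d = np.sqrt(((cent[:, None, :] - cent[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_d:
            return cent
        if attempt % 50 == 49:
            amp *= 1.2
    raise RuntimeError("could not place separated cluster centroids")


def simulate_genomes(cfg: SimulationConfig) -> tuple[GenomeSet, TruthSet]:
    cfg.validate()
    count_rng = np.random.default_rng([cfg.seed, _COUNT_STREAM])
    n_snps = int(count_rng.binomial(cfg.host_genome_len, cfg.snp_divergence_rate))
    n_indels = int(count_rng.binomial(cfg.host_genome_len, cfg.indel_divergence_rate))

    rng = np.random.default_rng([cfg.seed, _GENOME_STREAM])
    pathogen = random_genome(cfg.pathogen_genome_len, cfg.gc_content, rng)
    host = random_genome(cfg.host_genome_len, cfg.gc_content, rng)

    variants = _place_variants(cfg, host, n_snps, n_indels, rng)
    strain = apply_variants(host, variants)

    genes = tile_genes(PATHOGEN_REF_ID, cfg.pathogen_genome_len,
                       cfg.n_genes_pathogen, rng, "bbg")
    genes += tile_genes(HOST_REF_ID, cfg.host_genome_len,
                        cfg.n_genes_host, rng, "tcg")

    profiles = _cluster_centroids(cfg, rng)

    labels: dict[str, int] = {}
    for org_genes in (genes[: cfg.n_genes_pathogen], genes[cfg.n_genes_pathogen :]):
        lab = np.arange(len(org_genes)) % cfg.n_clusters
        lab = lab[rng.permutation(len(org_genes))]
        for g, c in zip(org_genes, lab):
            labels[g.gene_id] = int(c)

    abundance = {
        g.gene_id: float(v)
        for g, v in zip(genes, rng.lognormal(0.0, cfg.abundance_sigma, len(genes)))
    }
    boosted = genes[int(rng.integers(cfg.n_genes_pathogen))].gene_id
    abundance[boosted] *= 50.0

    genomes = GenomeSet(
        pathogen={PATHOGEN_REF_ID: pathogen},
        host_reference={HOST_REF_ID: host},
        host_strain={HOST_REF_ID: strain},
    )
    truth = TruthSet(
        true_variants=variants,
        gene_models=genes,
        true_cluster_labels=labels,
        true_profiles=profiles,
        gene_abundance=abundance,
        boosted_gene=boosted,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _expression_weights(
    genes: list[GeneModel], truth: TruthSet, t_index: int
) -> np.ndarray:
    w = np.array(
        [
            truth.gene_abundance[g.gene_id]
            * 2.0 ** truth.true_profiles[truth.true_cluster_labels[g.gene_id], t_index]
            for g in genes
        ]
    )
    return w / w.sum()


def _sample_fragments(
    source: np.ndarray,
    spans: np.ndarray,  # (n_genes, 2) usable [lo, hi) per gene on `source`
    gene_idx: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = len(gene_idx)
    flen = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, m)).astype(int)
    flen = np.maximum(flen, cfg.read_len)
    lo, hi = spans[gene_idx, 0], spans[gene_idx, 1]
    flen = np.minimum(flen, hi - lo)  # fragment longer than gene+flank: shrink
    start = lo + np.floor(rng.random(m) * (hi - lo - flen + 1)).astype(int)
    R = cfg.read_len
    s1 = np.empty((m, R), dtype=np.uint8)
    s2 = np.empty((m, R), dtype=np.uint8)
    for i in range(m):
        frag = source[start[i] : start[i] + flen[i]]
        s1[i] = frag[:R]
        s2[i] = revcomp(frag[-R:])
    return s1, s2, start


def _inject_errors(
    seq: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mutate bases in place per the calibrated quality model; return the
    Phred matrix matching the injected error probabilities."""
    m, L = seq.shape
    qm = cfg.quality_model
    err = np.full((m, L), cfg.base_error_rate)
    q_body = error_to_phred(cfg.base_error_rate, qm.max_phred)
    qual = np.full((m, L), q_body, dtype=np.uint8)
    if qm.tail_prob > 0 and qm.tail_len > 0:
        tail_rows = rng.random(m) < qm.tail_prob
        tl = min(qm.tail_len, L)
        err[tail_rows, L - tl :] = qm.tail_error_rate
        qual[tail_rows, L - tl :] = error_to_phred(qm.tail_error_rate, qm.max_phred)
    hit = rng.random((m, L)) < err
    n_hit = int(hit.sum())
    if n_hit:
        old = CODE_OF[seq[hit]].astype(np.int64)
        seq[hit] = BASES[(old + rng.integers(1, 4, size=n_hit)) % 4]
    return qual


def simulate_reads(
    genomes: GenomeSet, truth: TruthSet, cfg: SimulationConfig
) -> dict[tuple[str, int], ReadBatch]:
    """Per time point x replicate paired reads; host reads come from the
    DIVERGENT strain genome. Updates truth.read_origins."""
    cfg.validate()
    host_genes = truth.host_genes()
    path_genes = truth.pathogen_genes()
    strain = genomes.host_strain[HOST_REF_ID]
    pathogen = genomes.pathogen[PATHOGEN_REF_ID]

    # usable span per gene on its SOURCE genome (host genes lifted to strain)
    lift = CoordinateLift(truth.true_variants, len(genomes.host_reference[HOST_REF_ID]))
    fl = cfg.gene_flank

    def spans_for(genes, source_len, lifted):
        spans = np.empty((len(genes), 2), dtype=int)
        for i, g in enumerate(genes):
            a, b = (lift.lift_interval(g.start, g.end) if lifted
                    else (g.start, g.end))
            spans[i] = (max(0, a - fl), min(source_len, b + fl))
        return spans

    host_spans = spans_for(host_genes, len(strain), lifted=True)
    path_spans = spans_for(path_genes, len(pathogen), lifted=False)

    batches: dict[tuple[str, int], ReadBatch] = {}
    for ti, tp in enumerate(cfg.timepoints):
        w_host = _expression_weights(host_genes, truth, ti)
        w_path = _expression_weights(path_genes, truth, ti)
        for rep in range(1, cfg.replicates_per_timepoint + 1):
            rng = np.random.default_rng([cfg.seed, _READ_STREAM, ti, rep])
            sample = f"{tp}-r{rep}"
            n = cfg.reads_per_sample
            n_path = int(rng.binomial(n, cfg.pathogen_read_fraction[ti]))
            n_host = n - n_path

            parts = []
            for org, m, genes, spans, weights, source in (
                ("pathogen", n_path, path_genes, path_spans, w_path, pathogen),
                ("host", n_host, host_genes, host_spans, w_host, strain),
            ):
                if m == 0:
                    continue
                gidx = rng.choice(len(genes), size=m, p=weights)
                s1, s2, starts = _sample_fragments(source, spans, gidx, cfg, rng)
                q1 = _inject_errors(s1, cfg, rng)
                q2 = _inject_errors(s2, cfg, rng)
                parts.append((org, genes, gidx, starts, s1, q1, s2, q2))

            ids: list[str] = []
            seq1, qual1, seq2, qual2 = [], [], [], []
            serial = 0
            for org, genes, gidx, starts, s1, q1, s2, q2 in parts:
                for j in range(len(gidx)):
                    g = genes[gidx[j]]
                    rid = (
                        f"sim:{sample}:{serial:06d}|{org}|{g.gene_id}|{starts[j]}"
                    )
                    ids.append(rid)
                    truth.read_origins[rid] = ReadOrigin(
                        org, g.gene_id, int(starts[j]), sample
                    )
                    serial += 1
                seq1.append(s1); qual1.append(q1)
                seq2.append(s2); qual2.append(q2)

            R = cfg.read_len
            empty = np.empty((0, R), dtype=np.uint8)
            batches[(tp, rep)] = ReadBatch(
                sample=sample,
                timepoint=tp,
                replicate=rep,
                ids=ids,
                seq1=np.vstack(seq1) if seq1 else empty,
                qual1=np.vstack(qual1) if qual1 else empty,
                seq2=np.vstack(seq2) if seq2 else empty,
                qual2=np.vstack(qual2) if qual2 else empty,
                len1=np.full(n, R, dtype=int),
                len2=np.full(n, R, dtype=int),
            )
    return batches


# ---------------------------------------------------------------------------
# matrix-level generators for the co-expression and assay stages
# ---------------------------------------------------------------------------

def simulate_profile_matrix(
    n_genes: int,
    timepoints: int = 4,
    n_clusters: int = 8,
    noise_sd: float = 0.2,
    separation: float = 10.0,
    amplitude: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gene x timepoint log-profiles with planted, well-separated clusters.

    Centroid pairwise distance is at least `separation * noise_sd`.
    Returns (profiles, labels, centroids).
    """
    rng = np.random.default_rng(seed)
    min_d = separation * noise_sd
    amp = amplitude
    for attempt in range(500):
        cent = rng.normal(0.0, amp, size=(n_clusters, timepoints))
        d = np.sqrt(((cent[:, None] - cent[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_d:
            break
        if attempt % 50 == 49:
            amp *= 1.2
    labels = np.arange(n_genes) % n_clusters
    labels = labels[rng.permutation(n_genes)]
    X = cent[labels] + rng.normal(0.0, noise_sd, size=(n_genes, timepoints))
    df = pd.DataFrame(
        X,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"t{j}" for j in range(timepoints)],
    )
    return df, labels, cent


def simulate_mortality(
    days: int = 10,
    treated_daily_rate: float = 0.08,
    control_daily_rate: float = 0.01,
    n_insects: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cumulative mortality table for the Abbott-correction demo."""
    rng = np.random.default_rng(seed)
    rows = []
    dead_t = dead_c = 0
    for day in range(1, days + 1):
        dead_t += int(rng.binomial(n_insects - dead_t, treated_daily_rate))
        dead_c += int(rng.binomial(n_insects - dead_c, control_daily_rate))
        rows.append((day, dead_t, n_insects, dead_c, n_insects))
    return pd.DataFrame(
        rows,
        columns=["day", "treated_dead", "treated_total",
                 "control_dead", "control_total"],
    )


def simulate_qpcr(
    targets: tuple[str, ...] = ("grg1", "bqo", "pi9", "mtd"),
    references: tuple[str, ...] = ("tubulin",),
    samples: tuple[str, ...] = ("3h", "12h", "48h", "72h"),
    seed: int = 0,
    cq_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthetic long-format Cq table (sample, gene, role, Cq, efficiency)."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in references:
        base = rng.uniform(18, 22)
        for s in samples:
            rows.append((s, gene, "reference", base + rng.normal(0, cq_sd), 2.0))
    for gene in targets:
        base = rng.uniform(22, 30)
        trend = rng.normal(-1.0, 0.5)  # targets get more abundant over time
        for i, s in enumerate(samples):
            rows.append(
                (s, gene, "target", base + trend * i + rng.normal(0, cq_sd), 2.0)
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "role", "Cq", "efficiency"])
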