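# Methods

`dualseq` re-implements, at desk scale and with recorded ground truth, the
computational core of a dual RNA-seq analysis of a fungal entomopathogen
(*Beauveria bassiana*-like) infecting an insect host (*Tribolium
castaneum*-like): sequential two-genome read partitioning, iterative
SNP-correction of a strain-divergent host reference, FPKM quantification
with presence-set analysis, and UPGMA/Davies–Bouldin reduction of the
temporal co-expression structure. Every stage operates on synthetic data
whose generating parameters are known, so the pipeline is evaluated by
parameter recovery rather than by comparison with an external dataset.

## Synthetic data model

**Genomes.** Both genomes are i.i.d. base sequences at a configured GC
content (default 0.5), with no repeat structure, so unique mapping
behaviour is predictable. Defaults: 100 kb host, 50 kb pathogen. Each
genome is tiled end-to-end by non-overlapping single-exon genes (host
200, pathogen 100; lengths jittered ±20% around the mean).

**Host strain divergence.** The sequenced insects are never the strain of
the reference assembly. The strain genome differs from the host reference
by substitutions (default rate 5×10⁻³/bp) and short indels (2×10⁻⁴/bp,
lengths 1–8, 50/50 insertion/deletion). The substitution *count* is a
Binomial(L, rate) draw; *placement* is a mixture: a fraction (default
0.12) is concentrated in a few dense hotspots (3 hotspots, 0.06
substitutions/bp) and the rest is uniform. Clustered divergence is the
realistic regime (real strain divergence is strongly overdispersed) and
it is what makes iterative correction meaningful: with the alignment
threshold `L,-4,-0.5` a 100 bp read tolerates ~9 high-quality mismatches,
so under purely uniform 0.5% divergence essentially every read already
maps to the uncorrected reference and a second correction pass would have
nothing left to find. The hotspot geometry is chosen from the threshold
arithmetic: a read entering a hotspot stays mappable for roughly
9/0.06 ≈ 150 bp, so iteration 1 corrects the hotspot edges and iteration
2 reaches the interior — two passes clear a ~330 bp hotspot, reproducing
the mechanism behind a declining detected-SNP count across iterations.

**Reads.** Per time point (defaults "3h","12h","48h","72h") × replicate
(3) the generator emits paired 2×100 bp reads (fragment length
N(300, 30²)) at 50,000 pairs/library. The pathogen read share rises
0.002% → 0.0063% across time points — a deliberately tiny minority, which
is why the pathogen side of the analysis pools replicates. Host fragments
are drawn from the *divergent strain*, pathogen fragments from the
pathogen genome, with expression-weighted gene sampling (lognormal basal
abundance × 2^(cluster profile)). Read names encode the true origin for
truth lookups, and a name-scrambling test enforces that no downstream
code ever reads them.

**Errors and qualities.** Per-base error probabilities drive both error
injection and the Phred string (Q = −10·log₁₀ p, capped at 40), i.e.
qualities are calibrated. A two-state model adds an optional low-quality
3′ tail (default: 15% of reads carry a 12 nt tail at 5% error ≈ Q13) so
the sliding-window trimmer has something real to remove.

**Planted co-expression.** Cluster centroids (default K = 8) are drawn in
log₂ space and re-drawn until pairwise separation ≥ 10× the
within-cluster SD (default 0.2); genes receive centroid + Gaussian noise.
A matrix-level generator (`simulate_profile_matrix`) exposes the same
model without the read layer for clustering studies.

**What the generator does not emulate:** introns/splicing, adapter
contamination, PCR duplicates, strand-specific chemistry, repeat
sequence, GC-coverage bias, and biological replicate variation beyond
resampling noise. Passing tests therefore demonstrate correctness of the
algorithms under their stated models, not robustness to every artefact of
real libraries.

## Trimming

5′→3′ sliding window of 3 nt; truncate at the first window whose mean
Phred falls below the threshold (Q15 — the window quality is not part of
the published rule, so the common SLIDINGWINDOW practice is the default
and it is configurable); discard reads shorter than 36 nt, dropping the
mate with them (configurable to keep orphans).

## Alignment

A minimal *unspliced* seed-and-extend aligner stands in for the original
spliced mapper — the synthetic genomes are intron-free, and the two
contracts that matter downstream are preserved exactly:

* **Score threshold** f(L) = A + B·L with A = −4, B = −0.5 (match 0,
  mismatch −6, gap open −5, gap extend −3; a gap of length g costs
  open + g·extend). A placement is emitted only when score ≥ f(L).
  The mismatch penalty is a constant −6 (the high-quality value of the
  usual quality-scaled scheme); at the simulated qualities scaling would
  change nothing while complicating the exactness argument below.
* **Unique mapping**: the number of distinct loci attaining the best
  score is counted (tie margin 0 — exact ties only, deterministic and
  conservative); non-unique reads are reported with `mapping_count > 1`
  and excluded from pileups and counting.

Candidates come from exact k-mer seeds (k = 20) at non-overlapping read
offsets plus a terminal seed, on both strands. Each candidate window is
verified ungapped first; a windowed affine-gap DP (Gotoh, free reference
ends, global in the read) runs only when the ungapped comparison shows
≥ 2 effective mismatches. This fast path is *exact*: the cheapest gap
costs open+extend = 8 > 6, so no gapped alignment can beat an ungapped
placement with ≤ 1 mismatch. The DP window pad (16 bp) exceeds the
largest simulated indel. CIGARs for gapped winners come from a full
traceback; numerically all scores are integer-valued so float equality in
the traceback is exact.

The SNP-aware index preserves the final-index contract behaviourally
rather than format-identically: a read base matching any registered
alternate allele incurs no mismatch penalty (per-site allowed-base sets),
and a registered indel is traversable without gap penalty (served as an
alternative window haplotype with the indel applied; one indel per extra
view — co-occurring registered indels within one 130 bp window are not
combined, which the simulated indel density makes irrelevant). With an
empty variant set it is bit-identical to the plain index.

Mates are aligned independently (concordance is not enforced); a pair
counts as mapped when at least one mate places uniquely.

## Partitioning

All pairs are tried against the pathogen genome first; only failures
proceed to the host genome. Pathogen assignments are final. The
cross-mapping diagnostic re-tests pathogen-assigned pairs against the
host genome and reports the count without reassigning — mirroring the
control that mapping order does not distort expression.

## Reference polishing

Per iteration (default 2, matching the published procedure; a
convergence stop is available): align → pileup → call → conditionally
replace. Iteration 2 re-calls from scratch against the once-corrected
genome.

**Pileup.** Bases are projected through CIGARs; insertions attach to the
left anchor site, deletions leave their columns empty, non-ACGT bases are
skipped and counted. Per site and base the pileup keeps sufficient
statistics (count, ΣQ, Σlog₁₀(1−e)) — the genotype posterior below
depends on the data only through these sums, which allows fully
vectorised accumulation.

**Site quality.** The published rule specifies only a QUAL threshold, not
a model, so the caller defines an explicit independent-error posterior: a
base with Phred Q is wrong with probability e = 10^(−Q/10), uniformly
over the three other bases; genotypes are the four haploid bases under a
flat prior; QUAL = −10·log₁₀ P(reference genotype | data). One alternate
read at Phred Q gives QUAL = Q + 10·log₁₀3 exactly (checked
analytically). An alternate allele needs ≥ 2 supporting reads (guards
against lone sequencing errors; configurable). Substitution calls within
3 bp of a supported indel are suppressed — reads whose tail crosses an
indel score better with a terminal mismatch than with a gap and would
otherwise plant systematic false substitution evidence at indel flanks
(the usual indel-proximity filter of pileup callers).

**Correction.** A base is replaced only when QUAL > 5.0 (*strictly*
greater) AND exactly one alternate substitution allele is supported.
Indels are called (from gapped alignments, with a nominal Phred-30
observation weight, a documented heuristic since gaps carry no per-base
quality) but never applied — they enter only the final SNP-aware index,
together with unapplied multi-allelic substitutions. Substitution-only
correction conserves genome length. The haploid site model treats the
insect pool's residual polymorphism as multi-allelic sites routed to the
SNP-aware index rather than as genotypes.

**Stage mapping rates** are reported for {raw, after iteration 1, after
iteration 2, SNP-aware index}, computed as uniquely-mapped mates over all
mates with the same read set at every stage.

## Quantification

Fragments (pairs) are assigned to the single gene containing the midpoint
of their leftmost-to-rightmost span — single-exon synthetic genes make an
isoform EM pointless; the FPKM formula is the standard one,
FPKM_g = count_g / ((len_g/10³)·(total/10⁶)), and the length-weighted
FPKM sum identity (Σ FPKM·len/10³ = 10⁶·assigned/total) is enforced to
1e−9 in tests. Pathogen replicates are pooled (counts and totals summed
*before* FPKM) per time point; host replicates are kept separate, with
pooling available. A gene is "present" at FPKM > 0 by default (the
detection threshold is otherwise undefined; configurable); presence sets
yield all 2⁴−1 exclusive Venn regions, per-time-point specific counts and
percentages of the detected universe.

## Co-expression reduction

Each gene's (pooled) time course is divided by its own across-timepoint
mean and log₂-transformed — profiles become shape-comparable and
scale-invariant; rows containing zeros receive a pseudocount of 1 FPKM
before the ratio, all-zero rows are dropped and reported. Distances are
Euclidean by default (correlation available): the conventional companion
of UPGMA, and the Davies–Bouldin index is defined over a metric space.

UPGMA is size-weighted average linkage with a deterministic tie-break
(lexicographically smallest pair of smallest-member leaf ids); merge
heights are checked non-decreasing. The dendrogram is cut at every K in
[2, ⌈n/2⌉] (capped at 400) and each cut is scored with
DB = (1/K) Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ (Sᵢ mean member-to-centroid distance,
singletons 0; coincident centroids make the pair ratio +∞). The
minimising K is chosen, ties to the smallest K, and the full trace is
exported — the published account is ambiguous between global minimisation
and a stopping heuristic, so the trace lets either reading be inspected.
Cluster activity is the intra-cluster mean profile, laid out row-major on
a fixed near-square grid in cluster-id order so snapshots of different
time points are positionally comparable.

## Assays

Abbott's correction (treated−control)/(1−control) with clamping to 0 when
treated < control (warned) and an error at control = 1. NRQ:
RQ_g,s = E_g^(Cq_g,cal − Cq_g,s), divided by the geometric mean of
reference-gene RQs per sample. Efficiencies default to 2.0 per gene and
the calibrator defaults to the first sample — neither is reported in the
study this emulates; both are explicit parameters.

## Problem sizes and numerical choices

The recovery studies (`dualseq.studies`) fix the following conditions:
polishing uses a 100 kb host at 0.5% substitution divergence with 15,000
error-free (or 0.2%-error) pairs ≈ 30× coverage and flat expression
weights (genome-wide coverage, as a WGS-style correction input);
partitioning uses ~25,000 host + ~250 pathogen pairs (50,000 + 500
reads); aligner-vs-DP equivalence uses 200 reads of 40–60 bp with ≤ 2
substitutions plus ≤ 1 indel ≤ 5 bp against 2 kb (bounding mutation
events below the seed count guarantees a surviving exact seed by
pigeonhole, which is what makes exact agreement a provable property
rather than a tendency); cluster recovery uses 500 genes × 4 time points,
8 planted clusters at 10× separation, 20 seeded replicates. The analysis
drivers run the full 12-library default design and subsample the polish
input to 30,000 pairs (~60× coverage — calling saturates well below
that).

All coordinates are 0-based half-open internally; SAM, VCF and GFF3
writers convert on output. All randomness flows from named
`numpy.random.default_rng([seed, stream, ...])` child streams, so every
artefact is reproducible from one integer.

## Known limitations

Uniqueness counting only sees seeded candidates, so a co-optimal locus
sharing no exact seed with the read would be missed (irrelevant for
repeat-free i.i.d. genomes). QUAL values are not numerically those of any
specific production caller — only the threshold semantics are contracted.
Long indels (cost > |f(L)|) are unmappable end-to-end without
soft-clipping and therefore uncallable; the generator's indel length cap
keeps the simulation inside the mappable regime. The grid layout of the
activity map is presentational and fixed, not optimised.
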