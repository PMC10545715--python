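"""FPKM quantification, replicate pooling, presence sets and per-organism
read fractions.

A fragment (read pair) is assigned to the single-exon gene containing
the midpoint of its leftmost-to-rightmost alignment span; fragments
hitting no gene still count toward the mapped total. FPKM follows the
standard definition
    FPKM_g = count_g / ((length_g / 1e3) * (total_mapped / 1e6)).
Pathogen replicates are pooled per time point before FPKM (the fungal
read share is tiny); host replicates stay per-replicate by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .align import PairAlignment
from .genes import GeneModel


@dataclass
class ExpressionMatrix:
    fpkm: pd.DataFrame              # genes x samples
    meta: pd.DataFrame              # index samples; organism/timepoint/replicate
    totals: pd.Series               # total mapped fragments per sample

    def __post_init__(self):
        if not set(self.fpkm.columns) <= set(self.meta.index):
            raise ValueError("metadata must cover every sample column")
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM must be non-negative")


@dataclass
class PresenceSets:
    sets: dict[str, set]                       # per-timepoint expressed genes
    region_counts: dict[frozenset, int]        # exclusive Venn regions
    specific_counts: dict[str, int]
    union_size: int
    threshold: float
    percentages: dict[str, float] = field(default_factory=dict)
    specific_percentages: dict[str, float] = field(default_factory=dict)


class _GeneLocator:
    def __init__(self, genes: list[GeneModel]):
        self.by_ref: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for ref in {g.reference_id for g in genes}:
            sub = sorted(
                (g for g in genes if g.reference_id == ref), key=lambda g: g.start
            )
            self.by_ref[ref] = (
                np.array([g.start for g in sub]),
                np.array([g.end for g in sub]),
                [g.gene_id for g in sub],
            )

    def locate(self, ref: str, point: int) -> str | None:
        entry = self.by_ref.get(ref)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, point, side="right")) - 1
        if i >= 0 and point < ends[i]:
            return ids[i]
        return None


def count_fragments(
    alignments: list[PairAlignment], genes: list[GeneModel]
) -> tuple[pd.Series, int]:
    """Per-gene fragment counts (unique alignments only) and the total
    number of mapped fragments (gene-assigned or not)."""
    locator = _GeneLocator(genes)
    counts = pd.Series(0, index=[g.gene_id for g in genes], dtype=int)
    total = 0
    for pa in alignments:
        recs = pa.unique_records()
        if not recs:
            continue
        ref = recs[0].reference_id
        recs = [r for r in recs if r.reference_id == ref]
        total += 1
        span_start = min(r.position for r in recs)
        span_end = max(r.ref_end for r in recs)
        gid = locator.locate(ref, (span_start + span_end) // 2)
        if gid is not None:
            counts[gid] += 1
    return counts, total


def fpkm(
    counts: pd.Series, gene_lengths: pd.Series, total_mapped: int
) -> pd.Series:
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive (empty sample)")
    lengths = gene_lengths.reindex(counts.index)
    return counts / ((lengths / 1e3) * (total_mapped / 1e6))


def pool_replicates(
    counts_by_sample: dict[str, tuple[pd.Series, int]],
    groups: dict[str, str],
) -> dict[str, tuple[pd.Series, int]]:
    """Sum fragment counts and totals across the replicates of each group
    (time point) BEFORE FPKM computation."""
    pooled: dict[str, tuple[pd.Series, int]] = {}
    for sample, (counts, total) in counts_by_sample.items():
        group = groups[sample]
        if group in pooled:
            prev_counts, prev_total = pooled[group]
            if not prev_counts.index.equals(counts.index):
                raise ValueError(
                    f"mismatched gene universes pooling group {group!r}"
                )
            pooled[group] = (prev_counts + counts, prev_total + total)
        else:
            pooled[group] = (counts.copy(), total)
    return pooled


def expression_matrix(
    counts_by_sample: dict[str, tuple[pd.Series, int]],
    gene_lengths: pd.Series,
    meta: pd.DataFrame,
) -> ExpressionMatrix:
    cols = {
        s: fpkm(c, gene_lengths, t) for s, (c, t) in counts_by_sample.items()
    }
    return ExpressionMatrix(
        fpkm=pd.DataFrame(cols),
        meta=meta,
        totals=pd.Series({s: t for s, (_c, t) in counts_by_sample.items()}),
    )


def presence_sets(
    matrix: pd.DataFrame, threshold: float = 0.0
) -> PresenceSets:
    """Per-timepoint presence (FPKM > threshold), all exclusive Venn
    region counts and timepoint-specific counts. Expects one column per
    (pooled) time point."""
    tps = list(matrix.columns)
    sets = {t: set(matrix.index[matrix[t] > threshold]) for t in tps}
    union = set().union(*sets.values()) if sets else set()
    region_counts: dict[frozenset, int] = {}
    for r in range(1, len(tps) + 1):
        for inside in combinations(tps, r):
            region = set.intersection(*(sets[t] for t in inside))
            for t in tps:
                if t not in inside:
                    region -= sets[t]
            region_counts[frozenset(inside)] = len(region)
    specific = {t: region_counts[frozenset([t])] for t in tps}
    n_union = len(union)
    pct = {
        t: (100.0 * len(sets[t]) / n_union if n_union else 0.0) for t in tps
    }
    spct = {
        t: (100.0 * specific[t] / n_union if n_union else 0.0) for t in tps
    }
    return PresenceSets(
        sets=sets,
        region_counts=region_counts,
        specific_counts=specific,
        union_size=n_union,
        threshold=threshold,
        percentages=pct,
        specific_percentages=spct,
    )


def organism_fractions(
    partitions: dict[str, "PartitionResult"],
    sample_timepoints: dict[str, str],
) -> pd.DataFrame:
    """Pathogen/host mapped-read fractions per time point (replicates
    pooled) plus the per-sample breakdown."""
    rows = []
    for sample, part in partitions.items():
        rows.append(
            dict(
                sample=sample,
                timepoint=sample_timepoints[sample],
                pathogen=len(part.pathogen_alignments),
                host=len(part.host_alignments),
                unmapped=len(part.unmapped_ids),
            )
        )
    per_sample = pd.DataFrame(rows).set_index("sample")
    pooled = per_sample.groupby("timepoint")[["pathogen", "host", "unmapped"]].sum()
    mapped = pooled["pathogen"] + pooled["host"]
    pooled["pathogen_fraction"] = np.where(
        mapped > 0, pooled["pathogen"] / mapped, 0.0
    )
    pooled["host_fraction"] = np.where(mapped > 0, pooled["host"] / mapped, 0.0)
    per_sample_mapped = per_sample["pathogen"] + per_sample["host"]
    per_sample["pathogen_fraction"] = np.where(
        per_sample_mapped > 0, per_sample["pathogen"] / per_sample_mapped, 0.0
    )
    pooled.attrs["per_sample"] = per_sample
    return pooled


def top_expressed(
    matrix: pd.DataFrame, sample: str, n: int = 10
) -> pd.DataFrame:
    """Genes ranked by FPKM (descending), deterministic lexicographic
    tie-break on gene id."""
    col = matrix[sample]
    if n > len(col):
        warnings.warn(
            f"requested top {n} of {len(col)} genes: returning all"
        )
        n = len(col)
    df = col.rename("fpkm").rename_axis("gene_id").reset_index()
    df = df.sort_values(
        ["fpkm", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(n)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.set_index("rank")
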