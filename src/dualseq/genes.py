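"""Single-exon gene models and their GFF3 representation.

Synthetic genomes are tiled end-to-end by non-overlapping single-exon
genes, so a gene's length is simply end - start (0-based half-open
internally; GFF3 output is 1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    reference_id: str
    start: int  # 0-based half-open
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_genes(
    reference_id: str,
    genome_len: int,
    n_genes: int,
    rng: np.random.Generator,
    prefix: str,
    length_jitter: float = 0.2,
) -> list[GeneModel]:
    """Partition [0, genome_len) into n_genes contiguous genes with
    uniformly jittered lengths and random strands."""
    raw = rng.uniform(1.0 - length_jitter, 1.0 + length_jitter, size=n_genes)
    bounds = np.round(np.cumsum(raw) / raw.sum() * genome_len).astype(int)
    bounds[-1] = genome_len
    starts = np.concatenate([[0], bounds[:-1]])
    strands = rng.choice(list("+-"), size=n_genes)
    return [
        GeneModel(f"{prefix}_{i:05d}", reference_id, int(s), int(e), str(st))
        for i, (s, e, st) in enumerate(zip(starts, bounds, strands))
    ]


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.reference_id}\tdualseq\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ref, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            if ftype != "gene":
                continue
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genes.append(
                GeneModel(fields["ID"], ref, int(start) - 1, int(end), strand)
            )
    return genes
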