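"""FASTA / FASTQ file handling.

FASTA is wrapped at 60 columns; FASTQ is gzip-compressed Phred+33, one
file per mate. Reading goes through Biopython; the FASTQ writer is a
plain string formatter for throughput on large simulated batches.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .sequences import seq_to_array
from .simulate import ReadBatch


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            text = seq.tobytes().decode()
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {
        rec.id: seq_to_array(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fastq_pair(batch: ReadBatch, prefix) -> tuple[Path, Path]:
    """Write one library as <prefix>_R1.fastq.gz / <prefix>_R2.fastq.gz."""
    prefix = Path(prefix)
    paths = (
        prefix.with_name(prefix.name + "_R1.fastq.gz"),
        prefix.with_name(prefix.name + "_R2.fastq.gz"),
    )
    for mate, path in zip((1, 2), paths):
        seq, qual, lens = batch.mate(mate)
        with gzip.open(path, "wt") as fh:
            for i, rid in enumerate(batch.ids):
                L = int(lens[i])
                s = seq[i, :L].tobytes().decode()
                q = (qual[i, :L] + 33).astype(np.uint8).tobytes().decode()
                fh.write(f"@{rid}/{mate}\n{s}\n+\n{q}\n")
    return paths


def read_fastq_pair(path1, path2, sample: str = "", timepoint: str = "",
                    replicate: int = 0) -> ReadBatch:
    def load(path):
        ids, seqs, quals = [], [], []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                ids.append(rec.id.rsplit("/", 1)[0])
                seqs.append(seq_to_array(str(rec.seq)))
                quals.append(
                    np.asarray(rec.letter_annotations["phred_quality"],
                               dtype=np.uint8)
                )
        return ids, seqs, quals

    ids1, s1, q1 = load(path1)
    ids2, s2, q2 = load(path2)
    if ids1 != ids2:
        raise ValueError(f"mate files disagree on read ids: {path1} vs {path2}")

    def pack(seqs, quals):
        L = max((len(s) for s in seqs), default=0)
        n = len(seqs)
        sm = np.zeros((n, L), dtype=np.uint8)
        qm = np.zeros((n, L), dtype=np.uint8)
        lens = np.empty(n, dtype=int)
        for i, (s, q) in enumerate(zip(seqs, quals)):
            sm[i, : len(s)] = s
            qm[i, : len(q)] = q
            lens[i] = len(s)
        return sm, qm, lens

    sm1, qm1, l1 = pack(s1, q1)
    sm2, qm2, l2 = pack(s2, q2)
    return ReadBatch(
        sample=sample, timepoint=timepoint, replicate=replicate, ids=ids1,
        seq1=sm1, qual1=qm1, seq2=sm2, qual2=qm2, len1=l1, len2=l2,
    )
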