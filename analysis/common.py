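"""Shared helpers for the numbered analysis drivers: light TSV
(de)serialisation of alignment results so later stages don't re-align."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

from dualseq.align import AlignmentRecord, PairAlignment

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
ALN = ROOT / "scratch" / "aln"
RESULTS = ROOT / "results"

COLS = "read_id mate ref pos strand cigar score unique nloci".split()


def save_alignments(pairs: list[PairAlignment], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with gzip.open(path, "wt") as fh:
        fh.write("\t".join(COLS) + "\n")
        for pa in pairs:
            for rec in (pa.rec1, pa.rec2):
                if rec is None:
                    continue
                fh.write(
                    f"{pa.read_id}\t{rec.mate}\t{rec.reference_id}\t"
                    f"{rec.position}\t{rec.strand}\t{rec.cigar}\t"
                    f"{rec.score:g}\t{int(rec.is_unique)}\t{rec.mapping_count}\n"
                )


def load_alignments(path: Path) -> list[PairAlignment]:
    by_read: dict[str, PairAlignment] = {}
    empty = np.zeros(0, dtype=np.uint8)
    with gzip.open(path, "rt") as fh:
        header = fh.readline()
        assert header.split() == COLS
        for line in fh:
            rid, mate, ref, pos, strand, cigar, score, uniq, nloci = (
                line.rstrip("\n").split("\t")
            )
            rec = AlignmentRecord(
                read_id=rid, mate=int(mate), reference_id=ref,
                position=int(pos), strand=strand, cigar=cigar,
                score=float(score), is_unique=bool(int(uniq)),
                mapping_count=int(nloci), seq=empty, qual=empty,
            )
            pa = by_read.setdefault(rid, PairAlignment(rid, None, None))
            if rec.mate == 1:
                pa.rec1 = rec
            else:
                pa.rec2 = rec
    return list(by_read.values())
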