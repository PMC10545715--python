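"""Minimal SAM text output for alignment records (via pysam).

MAPQ is 60 for unique placements and 0 otherwise; CIGARs come straight
from the aligner (M/I/D). Positions convert from the library's 0-based
convention to SAM's 1-based on write (pysam handles this internally).
"""

from __future__ import annotations

import numpy as np
import pysam

from .align import AlignmentRecord


def write_sam(
    records: list[AlignmentRecord],
    genome: dict[str, np.ndarray],
    path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.seq.tobytes().decode()
            a.query_qualities = pysam.qualitystring_to_array(
                (rec.qual + 33).astype(np.uint8).tobytes().decode()
            )
            a.reference_id = ref_ids[rec.reference_id]
            a.reference_start = rec.position
            a.cigarstring = rec.cigar
            a.mapping_quality = 60 if rec.is_unique else 0
            flag = 0
            if rec.strand == "-":
                flag |= 16
            flag |= 64 if rec.mate == 1 else 128
            a.flag = flag
            a.set_tag("AS", int(rec.score))
            a.set_tag("NH", rec.mapping_count)
            out.write(a)
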