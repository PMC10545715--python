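"""Minimal VCF 4.2 writer/reader for the polishing calls.

POS is 1-based; multi-allelic sites are comma-joined on a single row;
QUAL carries the Phred-scaled site quality. The reader inverts the
writer exactly (round-trip contract), modulo QUAL text precision.
"""

from __future__ import annotations

from .polish import VariantCall


def write_vcf(calls: list[VariantCall], genome_meta: dict[str, int], path) -> None:
    """genome_meta maps reference id -> length. Calls must be sorted by
    (reference, position)."""
    keys = [(c.reference_id, c.position) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (reference, position)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dualseq-polish\n")
        for ref, length in genome_meta.items():
            fh.write(f"##contig=<ID={ref},length={length}>\n")
        fh.write(
            '##INFO=<ID=APPLIED,Number=0,Type=Flag,'
            'Description="Base replacement applied to the reference">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = "APPLIED" if c.applied else "."
            fh.write(
                f"{c.reference_id}\t{c.position + 1}\t.\t{c.ref}\t"
                f"{','.join(c.alts)}\t{c.qual:.6g}\t.\t{info}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, qual, _filt, info = (
                line.rstrip("\n").split("\t")[:8]
            )
            calls.append(
                VariantCall(
                    reference_id=chrom,
                    position=int(pos) - 1,
                    ref=ref,
                    alts=alt.split(","),
                    qual=float(qual),
                    applied="APPLIED" in info.split(";"),
                )
            )
    return calls
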