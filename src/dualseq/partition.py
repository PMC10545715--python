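"""Sequential two-genome read partitioning.

All reads are mapped first to the pathogen genome; only the reads that
fail there are then tried against the host genome. A pathogen-assigned
read is never reassigned — the cross-mapping diagnostic (how many
pathogen-assigned pairs could also be placed on the host genome) is
reported but has no effect on the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import KmerIndex, PairAlignment, PairedRead, ScoreParams, align_pair


@dataclass
class PartitionResult:
    pathogen_alignments: list[PairAlignment] = field(default_factory=list)
    host_alignments: list[PairAlignment] = field(default_factory=list)
    unmapped_ids: set[str] = field(default_factory=set)
    cross_mapped: int = 0
    per_organism_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return (
            len(self.pathogen_alignments)
            + len(self.host_alignments)
            + len(self.unmapped_ids)
        )

    def assigned_organism(self, read_id: str) -> str:
        if read_id in self.unmapped_ids:
            return "unmapped"
        for org, alns in (
            ("pathogen", self.pathogen_alignments),
            ("host", self.host_alignments),
        ):
            for pa in alns:
                if pa.read_id == read_id:
                    return org
        raise KeyError(read_id)


def partition_reads(
    pairs: list[PairedRead],
    pathogen_index: KmerIndex,
    host_index: KmerIndex,
    params: ScoreParams,
    compute_cross_mapped: bool = True,
) -> PartitionResult:
    result = PartitionResult()
    n = len(pairs)
    for pair in pairs:
        pa = align_pair(pair, pathogen_index, params)
        if pa.is_mapped:
            result.pathogen_alignments.append(pa)
            if compute_cross_mapped:
                if align_pair(pair, host_index, params).is_mapped:
                    result.cross_mapped += 1
            continue
        ha = align_pair(pair, host_index, params)
        if ha.is_mapped:
            result.host_alignments.append(ha)
        else:
            result.unmapped_ids.add(pair.read_id)
    if n:
        result.per_organism_fractions = {
            "pathogen": len(result.pathogen_alignments) / n,
            "host": len(result.host_alignments) / n,
            "unmapped": len(result.unmapped_ids) / n,
        }
    return result
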