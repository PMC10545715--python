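#!/usr/bin/env python
"""Generate the synthetic dual RNA-seq study: two genomes, a divergent
host strain, gene annotations and 12 paired-end libraries (4 time points
x 3 replicates) with the pathogen's read share rising from 0.002% to
0.0063%.

Writes FASTA/GFF3/FASTQ plus the ground truth under scratch/sim/ (bulky,
regenerable) and a small design summary under results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from dualseq.config import SimulationConfig
from dualseq.fastio import write_fasta, write_fastq_pair
from dualseq.genes import write_gff3
from dualseq.simulate import simulate_genomes, simulate_reads

from common import SIM as OUT  # noqa: E402
from common import RESULTS  # noqa: E402


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    cfg.to_json(OUT / "config.json")
    genomes, truth = simulate_genomes(cfg)

    write_fasta(genomes.pathogen, OUT / "pathogen.fa")
    write_fasta(genomes.host_reference, OUT / "host_reference.fa")
    write_fasta(genomes.host_strain, OUT / "host_strain.fa")
    write_gff3(truth.pathogen_genes(), OUT / "pathogen.gff3")
    write_gff3(truth.host_genes(), OUT / "host.gff3")

    batches = simulate_reads(genomes, truth, cfg)
    for (tp, rep), batch in batches.items():
        write_fastq_pair(batch, OUT / f"{tp}_r{rep}")

    with open(OUT / "truth.json", "w") as fh:
        json.dump(
            dict(
                variants=[(v.pos, v.ref, v.alt) for v in truth.true_variants],
                cluster_labels=truth.true_cluster_labels,
                profiles=truth.true_profiles.tolist(),
                boosted_gene=truth.boosted_gene,
                read_origins={
                    rid: [o.organism, o.gene_id, o.fragment_start, o.sample]
                    for rid, o in truth.read_origins.items()
                },
            ),
            fh,
        )

    n_snp = sum(v.is_snp for v in truth.true_variants)
    summary = pd.DataFrame(
        [
            ("host genome (bp)", cfg.host_genome_len),
            ("pathogen genome (bp)", cfg.pathogen_genome_len),
            ("injected substitutions", n_snp),
            ("injected indels", len(truth.true_variants) - n_snp),
            ("libraries", len(batches)),
            ("read pairs per library", cfg.reads_per_sample),
            ("planted co-expression clusters", cfg.n_clusters),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(RESULTS / "01_design_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nwrote genomes, annotations and {len(batches)} libraries to {OUT}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
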