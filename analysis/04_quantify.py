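#!/usr/bin/env python
"""FPKM expression matrices and presence-set (Venn) analysis.

Pathogen replicates are pooled per time point (their read share is tiny);
host replicates stay separate. Finds the pathogen's detected-gene set
expanding over infection time and reports the top-expressed pathogen
genes per time point.

Inputs: scratch/sim annotations + scratch/aln alignment tables from 02.
Outputs: FPKM/presence/top-gene tables under results/.
"""

import json
import sys

import pandas as pd

from common import ALN, RESULTS, SIM, load_alignments
from dualseq.config import SimulationConfig
from dualseq.genes import read_gff3
from dualseq.quantify import (
    count_fragments,
    expression_matrix,
    pool_replicates,
    presence_sets,
    top_expressed,
)


def main() -> None:
    cfg = SimulationConfig.from_json(str(SIM / "config.json"))
    path_genes = read_gff3(SIM / "pathogen.gff3")
    host_genes = read_gff3(SIM / "host.gff3")
    samples = [
        f"{tp}_r{rep}"
        for tp in cfg.timepoints
        for rep in range(1, cfg.replicates_per_timepoint + 1)
    ]
    tp_of = {s: s.rsplit("_", 1)[0] for s in samples}

    counts = {"pathogen": {}, "host": {}}
    for s in samples:
        counts["pathogen"][s] = count_fragments(
            load_alignments(ALN / f"{s}.pathogen.tsv.gz"), path_genes
        )
        counts["host"][s] = count_fragments(
            load_alignments(ALN / f"{s}.host.tsv.gz"), host_genes
        )

    # pathogen: pool replicates per time point before FPKM
    pooled = pool_replicates(counts["pathogen"], tp_of)
    pooled = {tp: pooled[tp] for tp in cfg.timepoints if pooled[tp][1] > 0}
    plen = pd.Series({g.gene_id: g.length for g in path_genes})
    pmeta = pd.DataFrame(
        dict(organism="pathogen", timepoint=list(pooled), replicate="pooled"),
        index=list(pooled),
    )
    pmat = expression_matrix(pooled, plen, pmeta)
    pmat.fpkm.round(6).to_csv(RESULTS / "04_pathogen_fpkm_pooled.tsv", sep="\t")

    # host: per-replicate FPKM
    hlen = pd.Series({g.gene_id: g.length for g in host_genes})
    hmeta = pd.DataFrame(
        dict(organism="host", timepoint=[tp_of[s] for s in samples],
             replicate=[s.rsplit("r", 1)[1] for s in samples]),
        index=samples,
    )
    hmat = expression_matrix(counts["host"], hlen, hmeta)
    hmat.fpkm.round(6).to_csv(RESULTS / "04_host_fpkm.tsv", sep="\t")

    # presence sets per organism (host pooled by mean over replicates)
    reports = {}
    for name, mat in (
        ("pathogen", pmat.fpkm),
        ("host", hmat.fpkm.T.groupby(hmeta["timepoint"]).mean().T[
            [tp for tp in cfg.timepoints]
        ]),
    ):
        ps = presence_sets(mat, threshold=0.0)
        reports[name] = dict(
            union=ps.union_size,
            per_timepoint={t: len(s) for t, s in ps.sets.items()},
            percent={t: round(p, 1) for t, p in ps.percentages.items()},
            specific=ps.specific_counts,
            specific_percent={
                t: round(p, 1) for t, p in ps.specific_percentages.items()
            },
            regions={
                "+".join(sorted(k)): v for k, v in ps.region_counts.items()
            },
        )
        rows = [
            dict(region="+".join(sorted(k)), genes=v)
            for k, v in ps.region_counts.items()
        ]
        pd.DataFrame(rows).to_csv(
            RESULTS / f"04_presence_regions_{name}.tsv", sep="\t", index=False
        )
    with open(RESULTS / "04_presence_summary.json", "w") as fh:
        json.dump(reports, fh, indent=2)

    # top expressed pathogen genes per pooled time point
    tops = []
    for tp in pmat.fpkm.columns:
        t = top_expressed(pmat.fpkm, tp, n=10).reset_index()
        t.insert(0, "timepoint", tp)
        tops.append(t)
    pd.concat(tops).to_csv(
        RESULTS / "04_pathogen_top10.tsv", sep="\t", index=False
    )

    for name, rep in reports.items():
        print(f"{name}: {rep['union']} genes detected overall; "
              f"per timepoint {rep['per_timepoint']} "
              f"({rep['percent']} % of detected set)")
    print("top pathogen gene per timepoint:")
    print(pd.concat(tops).groupby("timepoint").head(1).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
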