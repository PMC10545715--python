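#!/usr/bin/env python
"""Bioassay closed forms on synthetic tables: Abbott's control-mortality
correction of a feeding time-course and NRQ normalisation of a qPCR
validation panel against housekeeping references.

Outputs: input and corrected tables under results/.
"""

import sys

from common import RESULTS
from dualseq.assays import abbott_correct_table, nrq
from dualseq.simulate import simulate_mortality, simulate_qpcr


def main(seed: int = 1) -> None:
    mortality = simulate_mortality(seed=seed)
    mortality.to_csv(RESULTS / "06_mortality_input.tsv", sep="\t", index=False)
    corrected = abbott_correct_table(mortality)
    corrected.round(4).to_csv(
        RESULTS / "06_mortality_abbott.tsv", sep="\t", index=False
    )
    print("Abbott-corrected cumulative mortality:")
    print(corrected[["day", "treated_prop", "control_prop",
                     "corrected_mortality"]].round(3).to_string(index=False))

    cq = simulate_qpcr(seed=seed)
    cq.round(3).to_csv(RESULTS / "06_qpcr_input.tsv", sep="\t", index=False)
    out = nrq(cq, calibrator_sample="3h")
    out.round(4).to_csv(RESULTS / "06_qpcr_nrq.tsv", sep="\t")
    print("\nNRQ vs the 3h calibrator (tubulin reference):")
    print(out.round(3).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
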