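"""Closed-form bioassay computations: Abbott's control-mortality
correction and qPCR normalized relative quantities (NRQ).

Abbott:  corrected = (treated - control) / (1 - control).
NRQ:     RQ_{g,s} = E_g ^ (Cq_{g,calibrator} - Cq_{g,s});
         NRQ_{target,s} = RQ_{target,s} / geomean_ref RQ_{ref,s}.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def abbott_correct(treated_prop: float, control_prop: float) -> float:
    if not (0.0 <= treated_prop <= 1.0) or not (0.0 <= control_prop <= 1.0):
        raise ValueError("proportions must be in [0, 1]")
    if control_prop >= 1.0:
        raise ValueError("control mortality of 100% leaves nothing to correct")
    if treated_prop < control_prop:
        warnings.warn(
            "treated mortality below control mortality: clamping to 0"
        )
        return 0.0
    return (treated_prop - control_prop) / (1.0 - control_prop)


def abbott_correct_table(mortality: pd.DataFrame) -> pd.DataFrame:
    """Apply Abbott's correction to a cumulative mortality table with
    columns day, treated_dead, treated_total, control_dead, control_total."""
    out = mortality.copy()
    out["treated_prop"] = out["treated_dead"] / out["treated_total"]
    out["control_prop"] = out["control_dead"] / out["control_total"]
    out["corrected_mortality"] = [
        abbott_correct(t, c)
        for t, c in zip(out["treated_prop"], out["control_prop"])
    ]
    return out


def nrq(measurements: pd.DataFrame, calibrator_sample: str) -> pd.DataFrame:
    """Normalized relative quantities from a long-format Cq table with
    columns sample, gene, role ('target'|'reference'), Cq, efficiency.

    Every sample must carry a measurement for every reference gene; the
    divisor is the geometric mean of the reference-gene RQs per sample.
    Returns a samples x target-genes table of NRQ values.
    """
    required = {"sample", "gene", "role", "Cq", "efficiency"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    df = measurements.copy()
    if (df["Cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    if ((df["efficiency"] <= 1.0) | (df["efficiency"] > 2.2)).any():
        raise ValueError("efficiencies must lie in (1, 2.2]")
    samples = list(dict.fromkeys(df["sample"]))
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} absent")
    refs = sorted(df.loc[df["role"] == "reference", "gene"].unique())
    targets = sorted(df.loc[df["role"] == "target", "gene"].unique())
    if not refs:
        raise ValueError("at least one reference gene is required")

    cq = df.pivot_table(index="sample", columns="gene", values="Cq")
    eff = df.groupby("gene")["efficiency"].first()
    for s in samples:
        for g in refs:
            if pd.isna(cq.at[s, g]) if (s in cq.index and g in cq.columns) else True:
                raise ValueError(
                    f"missing reference measurement: sample {s!r}, gene {g!r}"
                )

    rq = pd.DataFrame(index=samples, columns=list(cq.columns), dtype=float)
    for g in cq.columns:
        rq[g] = eff[g] ** (cq.at[calibrator_sample, g] - cq.loc[samples, g])
    ref_geomean = np.exp(np.log(rq[refs]).mean(axis=1))
    out = pd.DataFrame(
        {g: rq[g] / ref_geomean for g in targets if g in rq.columns}
    )
    out.index.name = "sample"
    return out
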