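#!/usr/bin/env python
"""Accessible-interaction-space scans on the toy rigid-body fixtures.

Runs the clash-and-restraint placement scan on the three toy scenarios,
verifies the counts against each fixture's brute-force census, and traces
the restraint-application curve on the two-lobe fixture where the
degron-tail restraint (applied last) removes one placement lobe. Writes
results/ispace_counts.tsv and results/ispace_drop_curve.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from coreceptor import ispace, synthdata

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for scenario in ("census", "two_lobe", "symmetric"):
        toy = synthdata.gen_toy_structures(0, scenario)
        p = toy.scan_params
        result = ispace.scan(
            toy.receptor, toy.ligand, toy.restraints,
            grid_spacing=p["grid_spacing"], padding=p["padding"],
            n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
            canonicalize=p["canonicalize"],
        )
        for k in sorted(result.counts):
            rows.append(
                {
                    "scenario": scenario,
                    "min_restraints_satisfied": k,
                    "accessible_placements": result.counts[k],
                    "matches_census": result.counts[k] == toy.census[k],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "ispace_counts.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    assert df["matches_census"].all()
    print("\nScan counts equal the independent brute-force census on every fixture.")

    toy = synthdata.gen_toy_structures(0, "two_lobe")
    p = toy.scan_params
    curve = ispace.restraint_drop_curve(
        toy.receptor, toy.ligand, toy.restraints,
        grid_spacing=p["grid_spacing"], padding=p["padding"],
        n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
        canonicalize=p["canonicalize"],
    )
    labels = ["clash only"] + [
        f"+{r.source} restraint {i + 1}" for i, r in enumerate(toy.restraints)
    ]
    cdf = pd.DataFrame({"step": labels, "fully_consistent_placements": curve})
    cdf["relative_drop"] = [0.0] + [
        round(1 - b / a, 3) for a, b in zip(curve, curve[1:])
    ]
    cdf.to_csv(OUT / "ispace_drop_curve.tsv", sep="\t", index=False)
    print(cdf.to_string(index=False))
    print(
        "\nThe crosslink restraints barely reduce the accessible space; the "
        "degron-tail restraint applied last collapses it onto one lobe — the "
        "sharp non-linear drop the tail length imposes on the search."
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
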