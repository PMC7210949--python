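#!/usr/bin/env python
"""Segment synthetic AUX/IAA-like sequences into their five modules.

Generates seeded sequences with planted KR/degron/VKV motifs, recovers the
module architecture (DI, linker, core degron, degron tail, PB1) from
sequence alone, classifies per-residue disorder from synthetic score
profiles, and maps the lysine inventory onto the modules. Writes
results/annotation.tsv and prints the recovery summary.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from coreceptor import seqann, synthdata

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records, truth = synthdata.gen_sequences(seed=101, n_records=8, n_noncanonical=2)
    rng = np.random.default_rng(101)
    rows = []
    n_exact = 0
    for rec in records:
        ann = seqann.segment_domains(rec)
        expected = truth["records"][rec.id]
        exact = ann.canonical == expected["canonical"] and (
            not ann.canonical or ann.spans == expected["spans"]
        )
        n_exact += exact
        # synthetic disorder profile: high scores outside DI/PB1, low inside
        scores = np.clip(rng.uniform(0.55, 0.95, len(rec.sequence)), 0, 1)
        for name in ("DI", "PB1"):
            if name in ann.spans:
                s, e = ann.spans[name]
                scores[s - 1 : e] = rng.uniform(0.05, 0.35, e - s + 1)
        _, fractions = seqann.classify_disorder(
            seqann.DisorderProfile(protein_id=rec.id, scores=list(scores))
        )
        lys = seqann.lysine_positions(rec)
        site_map = seqann.map_sites(lys, ann)
        rows.append(
            {
                "protein": rec.id,
                "length": len(rec.sequence),
                "canonical": ann.canonical,
                "degron_span": str(ann.spans.get("degron", "-")),
                "tail_len": seqann.degron_tail_length(ann) if ann.canonical else -1,
                "frac_disordered": round(fractions["disordered"], 3),
                "n_lysines": len(lys),
                "lysines_in_tail": site_map.per_domain_counts.get("degron_tail", 0),
                "exact_recovery": exact,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "annotation.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        f"\nRecovered planted architecture exactly for {n_exact}/{len(records)} records "
        "(canonical spans tile each sequence; degron-free records flagged non-canonical)."
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
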