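#!/usr/bin/env python
"""Summarise mating-type idiomorph frequencies in the alkaloid panel.

In a heterothallic fungus, sexual crossing requires both idiomorphs; a
skewed A:B ratio is evidence that a region reproduces mostly clonally.
Ratios are always recomputed from the counts.
"""

import os

import pandas as pd

from clonoscope.chemotype import mating_summary
from clonoscope.table5 import expand_table5_fixture

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)


def main() -> None:
    profiles, _ = expand_table5_fixture()
    rows = []
    for s in mating_summary(profiles, group_by="region") + mating_summary(
        profiles, group_by="total"
    ):
        rows.append(
            {
                "group": s.group_id,
                "n": s.n,
                "n_A": s.n_a,
                "n_B": s.n_b,
                "n_ND": s.n_nd,
                "ratio_AB": round(s.ratio_ab, 2) if s.ratio_ab is not None else "NC",
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(OUT, "mating_types.csv"), index=False)
    print(df.to_string(index=False))
    print("note: per-genotype mating tallies are distributed across regions "
          "by a fixed convention for multi-region genotypes, so regional "
          "ratios are approximate for those few genotypes")


if __name__ == "__main__":
    main()
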