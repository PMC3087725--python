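#!/usr/bin/env python
"""Build the two analysis marker sets from the cleaned cohort.

Set 1: sliding-window LD pruning (r2 <= 0.2, 50-SNP windows, 5-SNP
steps).  Set 2: ancestry-informative markers — delta >= 0.3 between the
first two simulated ancestral frequency panels, then the same pruning.
The post-scan certifies the pruning contract (no retained within-window
pair above the ceiling).
"""
from pathlib import Path

import numpy as np
import pandas as pd

from admixcohort.io_formats import read_plink
from admixcohort.marker_sets import (delta_statistic, ld_prune,
                                     prune_violations, select_aims)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    g, v, s = read_plink(OUT / "clean")
    pruned = ld_prune(g, v)
    violations = prune_violations(g, v, pruned)
    print(f"LD pruning: {pruned.provenance['n_before']} -> {len(pruned)} "
          f"SNPs; post-scan violations: {violations}")
    pruned.write(v, OUT / "markers_pruned.txt")

    freqs = pd.read_csv(OUT / "cohort.freqs.tsv", sep="\t")
    full_v = read_plink(OUT / "cohort")[1]
    rsid_to_row = {r: i for i, r in enumerate(full_v["rsid"])}
    delta = np.zeros(g.n_variants)
    d_all = delta_statistic(freqs["pop1"].to_numpy(), freqs["pop2"].to_numpy())
    for col, rsid in enumerate(v["rsid"]):
        j = rsid_to_row[rsid]
        delta[col] = d_all[j] if j < len(d_all) else 0.0
    aims = select_aims(g, v, delta, delta_min=0.3)
    print(f"AIM selection: delta>=0.3 keeps "
          f"{aims.provenance['n_after_delta']} SNPs, pruned to {len(aims)}")
    aims.write(v, OUT / "markers_aims.txt")
    print(f"wrote {OUT}/markers_pruned.txt and {OUT}/markers_aims.txt")


if __name__ == "__main__":
    main()
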