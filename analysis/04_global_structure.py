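#!/usr/bin/env python
"""Global structure: genome-wide IBS with classical MDS, and genotype
PCA on the pruned marker set.

The MDS dimensions and leading PCs should separate the nearly
unadmixed group and spread the admixed groups along the ancestry
cline; the script reports how strongly dimension 1 / PC1 track the
simulated ancestry proportion.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from admixcohort.io_formats import read_plink
from admixcohort.structure_inference import classical_mds, ibs_matrix, pca
from analysis_util import load_markers

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    g, v, s = read_plink(OUT / "clean")
    markers = load_markers(v, OUT / "markers_pruned.txt")
    qtrue = pd.read_csv(OUT / "cohort.qtrue.tsv", sep="\t")
    q1 = qtrue.set_index("sample_id").loc[g.sample_ids, "Q1"].to_numpy()

    ibs = ibs_matrix(g.subset(variants=markers.indices))
    mds = classical_mds(ibs, n_dims=4)
    coords = pd.DataFrame(mds.coords, columns=[f"dim{i+1}" for i in range(4)])
    coords.insert(0, "sample_id", g.sample_ids)
    coords["group"] = s["group"].to_numpy()
    coords.to_csv(OUT / "mds_coords.tsv", sep="\t", index=False)

    pc = pca(g, markers, n_components=10)
    scores = pd.DataFrame(pc.scores[:, :4],
                          columns=[f"PC{i+1}" for i in range(4)])
    scores.insert(0, "sample_id", g.sample_ids)
    scores["group"] = s["group"].to_numpy()
    scores.to_csv(OUT / "pca_scores.tsv", sep="\t", index=False)
    pd.DataFrame(pc.scores,
                 columns=[f"PC{i+1}" for i in range(pc.scores.shape[1])]) \
        .assign(sample_id=g.sample_ids) \
        .to_csv(OUT / "pca_scores_full.tsv", sep="\t", index=False)

    print(f"MDS eigenvalues: {np.round(mds.eigenvalues, 2).tolist()}")
    print(f"PCA eigenvalues (top 4): {np.round(pc.eigenvalues[:4], 2).tolist()}")
    print(f"|corr(dim1, true ancestry)| = "
          f"{abs(np.corrcoef(mds.coords[:, 0], q1)[0, 1]):.3f}")
    print(f"|corr(PC1,  true ancestry)| = "
          f"{abs(np.corrcoef(pc.scores[:, 0], q1)[0, 1]):.3f}")
    print(f"wrote {OUT}/mds_coords.tsv, {OUT}/pca_scores.tsv")


if __name__ == "__main__":
    main()
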