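"""Cell dendrograms from covariance-overlap distances.

Computes the pairwise covariance overlap L of all cells from their weighted
mode subspaces, converts to arc distances d = arccos(L), and emits the
minimum spanning tree and the neighbor-joining tree in Newick form.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chromomodes import compare, gnm, hic_io, trees

OUT = Path("results/analysis")


def main() -> None:
    cells = sorted(p.name.split(".")[0] for p in OUT.glob("cell*.triplets.tsv"))
    if not cells:
        raise SystemExit("run 01_simulate_cohort.py first")
    modes = {}
    for cell in cells:
        cm = hic_io.read_triplets(OUT / f"{cell}.triplets.tsv",
                                  OUT / f"{cell}.bins.tsv")
        modes[cell] = gnm.modes_from_map(hic_io.filter_bins(cm), m=100,
                                         label=cell)
    n = len(cells)
    lmat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            lmat[i, j] = lmat[j, i] = compare.covariance_overlap_modesets(
                modes[cells[i]], modes[cells[j]])
    dmat = np.arccos(np.clip(lmat, 0, 1))
    pd.DataFrame(lmat, index=cells, columns=cells).to_csv(
        OUT / "cov_overlap.tsv", sep="\t")
    graph = trees.build_distance_graph(
        {"all": pd.DataFrame(dmat, index=cells, columns=cells)})
    mst = trees.minimum_spanning_tree(graph)
    njt = trees.neighbor_joining(graph)
    trees.write_newick(mst, OUT / "mst.nwk")
    trees.write_newick(njt, OUT / "nj.nwk")
    off = lmat[~np.eye(n, dtype=bool)]
    print(f"covariance overlap: mean {off.mean():.2f} "
          f"(range {off.min():.2f}-{off.max():.2f}) across {n} cells")
    print(f"MST total weight {mst.total_weight:.3f}; trees -> {OUT}")


if __name__ == "__main__":
    main()
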