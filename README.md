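# chromomodes

Comparative analysis of chromatin intrinsic dynamics across cell types,
using Gaussian network models (GNM) built from Hi-C contact maps.

A Hi-C experiment yields a symmetric matrix **M** whose entry M_ij counts
contacts between genomic loci *i* and *j* (here: uniform bins, 50 kb by
default). Treating the contact topology as an elastic network, the Kirchhoff
(graph Laplacian) matrix

    Γ_ij = −M_ij  (i≠j),    Γ_ii = Σ_{j≠i} M_ij

fully determines the equilibrium fluctuation statistics of the loci.
Its eigenvectors **u**_k (mode shapes) and eigenvalues λ_k (ascending;
1/λ_k is the statistical weight of mode k) give

* covariance over the softest m modes: C = Σ_{k≤m} λ_k⁻¹ **u**_k **u**_kᵀ,
* per-locus mobility (mean-square fluctuation): MSF_i = C_ii,
* directional cross-correlations D_ij = C_ij/√(C_ii C_jj).

On top of this single-cell-type machinery the package implements the
cross-cell-type comparisons:

* **mode-mode overlaps** [S(A,B)]_kl = |**v**_k^A · **v**_l^B| and
  *equivalent-mode* identification as a rectangular linear-assignment
  problem with cost 1 − S (Hungarian algorithm; the reference's first m
  modes search among the candidate's first 4m);
* **mode conservation** ⟨S⟩_k — the diagonal overlap averaged over all
  N(N−1)/2 cell pairs, before and after mode matching;
* **covariance overlap** L(A,B) ∈ [0,1] between whole weighted mode
  subspaces (weights w_k = λ_k⁻¹/Σ_l λ_l⁻¹), converted to an arc distance
  d_cov = arccos L, aggregated over chromosomes (maximum by default) into a
  cell–cell distance graph, and summarized as a minimum spanning tree
  (Prim) and a neighbor-joining tree;
* **highly-mobile-gene screening**: per-cell relative mobility
  Δ⟨Δr_i²⟩_q = MSF_q,i − (cohort mean), top 10% of loci called highly
  mobile, overlapping genes ("HMGs") screened against expression gene-set
  collections (GMT) by Jaccard index J = |∩|/|∪| and rank-ordered;
* **single-cell 3D models**: per-locus coordinates convert to contact
  frequencies via the inverse-cube law n = (k/d)³, and sparse single-cell
  maps can be summed element-wise into combined maps.

Because the analyses need ground truth to be testable, a first-class
synthetic-data module generates TAD-structured, distance-decaying contact
maps; families of cell types sharing mode shapes with *planted* reshufflings
of mode frequencies; planted highly mobile loci; gene annotations; and
gene-set collections enriched for the planted mobile genes.

## Worked example

The numbered scripts under `analysis/` run the full story on a synthetic
cohort of six cell types (300 loci, two chromosomes, planted permutations of
the first 20 mode frequencies, ten planted mobile loci per cell):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_gnm_modes.py
python analysis/03_mode_matching.py
python analysis/04_cell_trees.py
python analysis/05_mobility_screen.py
```

prints, among other lines:

```
mode conservation <S>_1 = 0.08 before, 0.87 after matching
profile correlation vs cell00: 0.66 before -> 0.75 after
covariance overlap: mean 0.55 (range 0.54-0.57) across 6 cells
cell00: 100% of planted mobile loci in the top 10%
cell00: self rank 1, top J = 0.250
```

Reading: before matching, cells disagree on which mode carries which
frequency rank (⟨S⟩₁ = 0.08 — the planted reshuffling), but the *shapes* are
shared, so reindexing each cell's modes by the Hungarian matching restores
near-perfect conservation (0.87) and raises mobility-profile correlations.
Every cell's highly-mobile-gene set ranks its own (contaminated) expression
set first in the screen — the planted truth is recovered end to end.

The same steps are available as a pipeline:
`chromomodes run --out runs/demo --seed 17` (also `simulate`, `gnm`,
`convert-structure` subcommands), writing TSV/Newick/GMT outputs plus a
manifest with SHA-256 checksums; reruns are byte-identical.

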