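# Methods

## Model

Each genomic locus (a uniform bin, default 50 kb) is a node of an elastic
network whose spring constants are the Hi-C contact counts M_ij. The
Kirchhoff matrix Γ (off-diagonals −M_ij, diagonal the contact degree) is a
weighted graph Laplacian: symmetric, positive semidefinite, with one zero
mode per connected component. Self-contacts (the diagonal of M) carry no
spring and are ignored. Under the Gaussian model the fluctuation covariance
is the pseudoinverse of Γ, approximated by the softest m modes,
C = Σ_{k≤m} λ_k⁻¹ u_k u_kᵀ. Everything downstream — mobility (MSF = diag C),
correlation cosines D, mode comparison, covariance overlap — is a function
of the eigenpairs.

The retained mode count defaults to m = 500; the softest few hundred modes
carry the collective, chromosome-scale dynamics, and truncation keeps the
cross-cell matching (cubic in the number of modes) cheap. For the synthetic
cohorts used in the tests and the analysis scripts, which have only a few
hundred loci, m = 100 (or the full spectrum) is used instead; m is always
clamped to n − 1 with a warning.

Two analysis scopes are supported: `genome` (one Γ over intra- plus
inter-chromosomal contacts — the default for mobility profiles) and
`chromosome` (per-chromosome Γ — used for correlation-cosine maps).
Inter-chromosomal counts are passed through unscaled.

## Numerical choices

* **Eigensolution.** Dense `eigh` up to 2 500 loci, sparse shift-invert
  Lanczos (`eigsh`, small negative shift so the factorization is
  nonsingular at λ = 0) above. An eigenvalue below 1e−10·λ_max counts as a
  zero mode; more than one zero mode raises and directs the caller to
  `filter_bins` (zero-contact bins dropped, largest connected component
  kept, with a mask so results re-index to original bins).
* **Sign and degeneracy conventions.** Each eigenvector is flipped so its
  largest-magnitude component is positive (overlaps use absolute values, so
  this only stabilizes serialized output). Within an eigenvalue cluster
  closer than a 1e−9 relative gap, modes are ordered by the index of their
  largest component; overlaps within such clusters are basis-dependent and
  documented as such.
* **Mode matching.** `scipy.optimize.linear_sum_assignment` on cost 1 − S,
  rectangular: the reference's first m modes search the candidate's first
  `window_factor`·m (default 4). Cost ties are resolved deterministically
  by the solver; they are measure-zero on real-valued overlaps.
* **Mask reconciliation.** Cells may miss different bins (e.g. centromeric
  bands). Before any cross-cell overlap, eigenvectors are restricted to the
  intersection of valid bins and re-normalized there.
* **Mode conservation.** ⟨S⟩_k is the mean (not the sum) of the diagonal
  overlap over all N(N−1)/2 unordered pairs, keeping it in [0,1].
* **Covariance overlap.** Variances are normalized to weights
  w_k = λ_k⁻¹/Σλ_l⁻¹ so cells with different total read counts compare
  directly; the inner bracket is clamped to [0,1] only for excursions below
  1e−9. Note 1 − √(bracket) amplifies machine-epsilon error to O(√ε) ≈ 1e−8
  on self-comparisons, and arccos near 1 amplifies further to ~1e−4 on arc
  distances; tests budget for this.
* **Trees.** Prim's MST is written in-package with an explicit
  (weight, label, label) heap key so ties break lexicographically and runs
  are reproducible; it is tested against brute-force enumeration over
  Prüfer sequences. Neighbor joining delegates to scikit-bio's Saitou–Nei
  implementation, which clamps negative branch lengths to zero and shifts
  the deficit to the sister branch; it is verified against the three-point
  closed form and exact recovery of additive distances. Emitted Newick
  files carry the true computed arc-distance branch lengths.
* **Inverse-cube law.** n = (k/d)³ diverges for coincident loci; an
  optional cap bounds it, and without a cap coincident loci raise. Resolved
  3D models have excluded volume, so the default is no cap. No balancing or
  normalization is ever applied to contact maps; raw counts are the model
  input.
* **Jaccard screening.** J(∅,∅) is defined as 0 so rankings are total;
  ranking ties break by candidate label. The top-10% mobility quantile is
  taken over all genome bins jointly by default (a per-chromosome mode
  exists behind a flag). A gene overlaps a bin if their half-open intervals
  share ≥ 1 bp.

## Synthetic data: what it emulates, and what it does not

`generate_contact_map` plants the qualitative features the analyses depend
on: power-law distance decay (contact ∝ |i−j|^−α, default α = 1, amplitude
100 counts at lag 1), multiplicative TAD blocks (boost ≥ 1 between
boundaries), a flat trans floor (default 1% of amplitude) so genome-scope
graphs stay connected, and multiplicative Gamma noise whose coefficient of
variation is `noise_level` (default 0.1 in the cohorts; Poisson-like in
spirit — variance grows with the mean — while keeping expectations exact
and maps strictly nonnegative).

`generate_cell_family` encodes the central hypothesis — cell types share
mode *shapes* but differ in mode *frequencies* — literally: a noisy copy of
the base map (lognormal, CV = `strength`; the copy's shapes drift from the
base's, which is what makes recovery nontrivial) is eigendecomposed and
reassembled with the first K nonzero eigenvalues permuted by the planted
bijection. Because eigenvalue differences among slow modes are comparable
to long-range contact entries, the reassembled map can contain negative
contacts. They are repaired with a *uniform additive floor*: raising every
pairwise contact by c adds the complete-graph Laplacian c(nI − J) to Γ,
which shifts all nonzero eigenvalues by exactly c·n and leaves every
eigenvector and the eigenvalue ordering untouched. (Clipping instead of
flooring was measured to destroy the planted ordering; the floor is exact.)
Planted highly mobile loci have their contacts scaled by `hm_weaken`
(default 0.5) *before* the floor, so they lose genuine contact strength and
gain mobility without becoming the slowest, localized modes of the cell.
`strength` defaults to 0.2; at 0.3 on a well-separated slow spectrum,
matched-shape overlaps stay around 0.9 and ≥ 90% of planted permutation
indices are recovered. TAD boundaries in the validation cohorts are
irregular by design: equal-sized blocks produce near-degenerate slow
eigenvalues for which a frequency rank is not well defined.

The generator does **not** emulate polymer-physics realism, compartment
checkerboards, library biases, or the true read-depth statistics of Hi-C;
passing tests demonstrate that the *operations* recover planted structure
under the stated noise, not that real cell types behave like the generator.

3D structures come from metric MDS (SMACOF, 3 components) on target
distances d = k·M^−1/3, with missing contacts pinned past the largest
finite distance; the embedding must reproduce the target's contact rank
order (Spearman > 0.8 on nonzero entries) or it raises. Gene annotations
tile the bins deterministically per seed; expression collections keep a
1 − contamination fraction of each planted HMG set (default contamination
0.2), refill to size, and add 30 random decoy sets of the median size.

## Problem sizes

Validation cohorts use 200–400 loci, 1–2 chromosomes, 3–6 cells, 10 seeds
per stochastic claim, and full or 100-mode spectra — small enough that the
whole suite and the reproduction script each run in tens of seconds on one
CPU, while exercising every code path the genome-scale configuration would.

## Known limitations

* The uniform repair floor makes family maps dense and additively shifts
  their spectra; mode shapes and order are exact, but absolute eigenvalues
  (hence absolute MSF scales) are not comparable between base and family
  maps. Comparisons are correlation- or overlap-based throughout, so no
  analysis here depends on the absolute scale.
* Genome-scope runs at real scale (≥ 5×10⁴ loci) rely on the sparse
  shift-invert path; it is exercised in tests only at small n (against the
  dense solver), not at full genome size.
* `replacement_fraction` reports equivalent modes drawn from beyond the
  candidate's first m; the alternative reading (any index change) is
  emitted as `changed_fraction`.
* Whether matched-mode mobility profiles should use the candidate's own
  eigenvalues or the reference's weights is genuinely open; the default is
  the candidate's own, and `reindex_modes` keeps both shapes and
  frequencies so either weighting can be applied downstream.
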