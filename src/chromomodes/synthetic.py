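"""Synthetic inputs with planted ground truth.

Real Hi-C maps show strong distance decay, TAD blocks on the diagonal and a
shared family of slow mode shapes across related cell types whose statistical
weights (frequencies) differ. The generators here plant exactly those
features so the downstream analyses can be tested against a known truth:

* ``generate_contact_map``: power-law distance decay with multiplicative TAD
  boosts and optional Poisson-like (Gamma multiplicative) noise;
* ``generate_cell_family``: spectral surgery on a base map — eigenvalues of
  the first K modes are re-assigned by a planted permutation while the mode
  shapes are kept, so cells share shapes but differ in frequencies;
  designated loci get their contacts weakened so their mobility rises;
* ``generate_gene_annotation`` / ``generate_heg_collection``: gene models
  tiling the bins and GMT collections enriched for the planted mobile genes;
* ``generate_structure``: a 3D embedding whose inverse-cube contact map
  matches a target in rank order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.manifold import MDS

from .errors import EmbeddingError, InvalidSpecError
from .gnm import build_kirchhoff
from .hic_io import ContactMap, Structure3D, n_connected_components, uniform_bins
from .screen import GeneAnnotation, GeneSet, GeneSetCollection


@dataclass
class SyntheticSpec:
    """Parameters of a planted contact map.

    Contacts between loci i, j of the same chromosome have expectation
    ``amplitude·|i−j|^−decay_exponent``, multiplied by ``intra_tad_boost``
    when no TAD boundary separates them. Trans contacts sit at a flat
    ``amplitude·trans_level`` floor so the genome-scope contact graph stays
    connected. ``noise_level`` is the coefficient of variation of
    multiplicative Gamma noise (0 = deterministic expectations).
    """

    n_loci: int
    bin_size: int = 50_000
    n_chromosomes: int = 1
    tad_boundaries: tuple[int, ...] = ()
    decay_exponent: float = 1.0
    intra_tad_boost: float = 1.0
    noise_level: float = 0.0
    amplitude: float = 100.0
    trans_level: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.tad_boundaries = tuple(int(b) for b in self.tad_boundaries)
        if self.n_chromosomes < 1 or self.n_loci < 3 * self.n_chromosomes:
            raise InvalidSpecError("need >= 3 loci per chromosome")
        if list(self.tad_boundaries) != sorted(set(self.tad_boundaries)):
            raise InvalidSpecError("tad_boundaries must be strictly increasing")
        if self.tad_boundaries and (self.tad_boundaries[0] < 0
                                    or self.tad_boundaries[-1] > self.n_loci):
            raise InvalidSpecError("tad_boundaries outside [0, n_loci]")
        for name in ("decay_exponent", "intra_tad_boost", "amplitude"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidSpecError(f"{name} must be finite and positive")
        if self.intra_tad_boost < 1:
            raise InvalidSpecError("intra_tad_boost must be >= 1")
        if self.noise_level < 0 or self.trans_level < 0:
            raise InvalidSpecError("noise_level/trans_level must be >= 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        base = self.n_loci // self.n_chromosomes
        rem = self.n_loci % self.n_chromosomes
        return {f"chr{i + 1}": base + (1 if i < rem else 0)
                for i in range(self.n_chromosomes)}


@dataclass
class PlantedPerturbation:
    """Ground truth for one synthetic cell type: a bijection on the first K
    mode indices (0-based) that reassigns mode frequencies, and the loci
    planted as highly mobile."""

    mode_permutation: tuple[int, ...]
    hm_loci: frozenset = frozenset()
    cell_label: str = ""

    def __post_init__(self):
        perm = tuple(int(p) for p in self.mode_permutation)
        if sorted(perm) != list(range(len(perm))):
            raise InvalidSpecError("mode_permutation is not a bijection on 0..K-1")
        self.mode_permutation = perm
        self.hm_loci = frozenset(int(i) for i in self.hm_loci)


def expected_contacts(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free expected contact matrix of a spec (the generator's own
    closed form, exposed for oracle use)."""
    n = spec.n_loci
    chrom_of = np.repeat(np.arange(spec.n_chromosomes),
                         list(spec.chrom_sizes.values()))
    # TAD segment id: increases at every boundary and at chromosome starts
    seg = np.zeros(n, dtype=int)
    for b in spec.tad_boundaries:
        seg[b:] += 1
    seg = seg + chrom_of * (len(spec.tad_boundaries) + 1)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lag = np.abs(i - j).astype(float)
    with np.errstate(divide="ignore"):
        cis = spec.amplitude * lag ** (-spec.decay_exponent)
    cis[lag == 0] = 0.0
    same_chrom = chrom_of[i] == chrom_of[j]
    same_tad = seg[i] == seg[j]
    m = np.where(same_chrom, cis, spec.amplitude * spec.trans_level)
    m = np.where(same_chrom & same_tad, m * spec.intra_tad_boost, m)
    np.fill_diagonal(m, 0.0)
    return m


def generate_contact_map(spec: SyntheticSpec) -> ContactMap:
    """A symmetric, nonnegative, distance-decaying contact map with TAD
    blocks; deterministic under the spec's seed."""
    mean = expected_contacts(spec)
    n = spec.n_loci
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        cv2 = spec.noise_level ** 2
        shape = 1.0 / cv2
        iu = np.triu_indices(n, k=1)
        noisy = np.zeros_like(mean)
        noisy[iu] = rng.gamma(shape, scale=mean[iu] / shape)
        m = noisy + noisy.T
    else:
        m = mean
    cm = ContactMap(
        bin_size=spec.bin_size,
        bins=uniform_bins(n, spec.bin_size, spec.chrom_sizes),
        matrix=m,
        provenance=f"synthetic(seed={spec.seed})",
    )
    if n_connected_components(cm) != 1 and spec.n_chromosomes == 1:
        raise InvalidSpecError("generated cis map is disconnected")
    return cm


def _repair_nonnegative(m: np.ndarray) -> np.ndarray:
    """Exact nonnegativity repair of implied contacts.

    Spectral reconstruction can leave negative implied contacts. Raising
    *every* pairwise contact by the same constant c adds c·(nI − J) — a
    complete-graph Laplacian — to Γ, which shifts all nonzero eigenvalues by
    exactly c·n and leaves every eigenvector and the eigenvalue ordering
    untouched (all nonzero modes are orthogonal to the all-ones vector). So
    the smallest implied contact is floored to zero by a uniform shift rather
    than clipped, and the planted mode structure survives the repair exactly.
    """
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    c = -min(float(m.min()), 0.0)
    if c > 0:
        m = m + c
        np.fill_diagonal(m, 0.0)
    return m


def generate_cell_family(base: ContactMap,
                         perturbations: list[PlantedPerturbation],
                         strength: float = 0.2,
                         seed: int = 0,
                         hm_weaken: float = 0.5) -> list[ContactMap]:
    """Cell types sharing the base's mode shapes with reshuffled frequencies.

    Each cell starts from a noisy copy of the base map (multiplicative
    lognormal noise with coefficient of variation ``strength``; strength 0
    copies the base exactly, so shapes stay recognizable — matched-shape
    overlaps stay above ~0.9 up to strength ≈ 0.3 on well-separated spectra).
    The copy's own Kirchhoff eigenpairs (λ'_k, u'_k) are then re-assembled as
    Γ'' = Σ_k λ'_{π(k)} u'_k u'_kᵀ over the first K nonzero modes (bijection
    π; base eigenvalues elsewhere), so the shape resembling base mode k
    surfaces at mode number π(k) in the new cell — shared shapes, reshuffled
    frequencies. Γ'' is converted back to a contact map with nonnegativity
    repair, and contacts of the planted ``hm_loci`` are scaled down by
    ``hm_weaken`` so their MSF rises.
    """
    if not 0 <= strength <= 1:
        raise InvalidSpecError("strength must be in [0, 1]")
    n = base.n_valid
    out = []
    rng = np.random.default_rng(seed)
    for pert in perturbations:
        K = len(pert.mode_permutation)
        if K > n - 1:
            raise InvalidSpecError("permutation longer than the nonzero spectrum")
        m = base.matrix
        if strength > 0:
            sigma = math.sqrt(math.log(1.0 + strength ** 2))
            z = rng.standard_normal((n, n))
            z = np.triu(z, 1)
            z = z + z.T
            m = m * np.exp(sigma * z - 0.5 * sigma ** 2)
        noisy = base.with_matrix(m, provenance=f"noisy({pert.cell_label})")
        vals, vecs = np.linalg.eigh(build_kirchhoff(noisy).matrix)
        new_vals = vals.copy()
        # vals[0] is the zero mode; nonzero mode k lives at column k+1
        for k, pk in enumerate(pert.mode_permutation):
            new_vals[k + 1] = vals[pk + 1]
        gamma_new = (vecs * new_vals) @ vecs.T
        m = -gamma_new
        np.fill_diagonal(m, 0.0)
        if pert.hm_loci:
            # weaken before the repair floor so the planted loci lose genuine
            # contact strength without dropping below the collective modes
            scale = np.ones(n)
            scale[sorted(pert.hm_loci)] = np.sqrt(hm_weaken)
            m = m * np.outer(scale, scale)
        m = _repair_nonnegative(m)
        cm = ContactMap(bin_size=base.bin_size, bins=base.bins, matrix=m,
                        valid_mask=base.valid_mask.copy(),
                        provenance=f"family({pert.cell_label})")
        if n_connected_components(cm) != 1:
            # guarantee connectivity with a vanishing trace of the base map
            cm = cm.with_matrix(m + 1e-9 * base.matrix,
                                provenance=cm.provenance + "+eps")
        out.append(cm)
    return out


def generate_gene_annotation(bins: pd.DataFrame | None = None,
                             n_loci: int | None = None,
                             bin_size: int = 50_000,
                             genes_per_bin: int = 1,
                             seed: int = 0) -> GeneAnnotation:
    """Gene models tiling the bins: ``genes_per_bin`` genes per bin, each
    covering a deterministic-per-seed subinterval of its bin."""
    if genes_per_bin < 1:
        raise InvalidSpecError("genes_per_bin must be >= 1")
    if bins is None:
        if n_loci is None:
            raise InvalidSpecError("give bins or n_loci")
        bins = uniform_bins(n_loci, bin_size)
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for b, row in bins.iterrows():
        width = row["end"] - row["start"]
        for g in range(genes_per_bin):
            lo = row["start"] + (g * width) // genes_per_bin
            hi = row["start"] + ((g + 1) * width) // genes_per_bin
            span = hi - lo
            off = int(rng.integers(0, max(span // 4, 1)))
            length = max(span // 2, 1)
            rows.append((f"G{gid:06d}", row["chrom"], lo + off,
                         min(lo + off + length, hi)))
            gid += 1
    return GeneAnnotation(records=pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end"]))


def genes_in_bins(ann: GeneAnnotation, bins: pd.DataFrame,
                  loci: set[int]) -> frozenset:
    """Gene ids overlapping the given original-bin indices (>=1 bp)."""
    sel = bins.iloc[sorted(loci)]
    hits = set()
    for _, g in ann.records.iterrows():
        ov = sel[(sel["chrom"] == g["chrom"]) & (sel["start"] < g["end"])
                 & (g["start"] < sel["end"])]
        if len(ov):
            hits.add(g["gene"])
    return frozenset(hits)


def generate_heg_collection(true_hmgs: dict[str, GeneSet],
                            universe: list[str],
                            n_decoy_sets: int = 30,
                            contamination: float = 0.2,
                            seed: int = 0) -> GeneSetCollection:
    """An expression gene-set collection enriched for the planted HMGs.

    For each true cell, a set keeping a (1−contamination) fraction of its
    HMGs, refilled to the original size with random genes, plus
    ``n_decoy_sets`` random sets of the median true-set size.
    """
    if not 0 <= contamination < 0.5:
        raise InvalidSpecError("contamination must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    sets = []
    sizes = [len(s.genes) for s in true_hmgs.values()] or [10]
    for cell, gs in true_hmgs.items():
        members = sorted(gs.genes)
        keep = len(members) - int(round(contamination * len(members)))
        kept = list(rng.choice(members, size=keep, replace=False)) if members else []
        pool = [g for g in universe if g not in gs.genes]
        fill = list(rng.choice(pool, size=len(members) - keep, replace=False))
        sets.append(GeneSet(label=cell, genes=frozenset(kept + fill),
                            description="synthetic highly-expressed genes"))
    size = int(np.median(sizes))
    for d in range(n_decoy_sets):
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        sets.append(GeneSet(label=f"decoy{d:03d}", genes=frozenset(members),
                            description="decoy gene set"))
    return GeneSetCollection(sets=sets)


def generate_structure(target: ContactMap, k_const: float = 1.0,
                       seed: int = 0,
                       min_spearman: float | None = 0.8) -> Structure3D:
    """A 3D embedding whose inverse-cube contacts track the target map.

    Target distances d_ij = k·M_ij^{−1/3} (missing contacts pinned just
    beyond the largest finite distance) are embedded in 3D by metric MDS.
    Raises if the round-trip Spearman correlation on nonzero entries falls
    below ``min_spearman`` (pass None to skip the check).
    """
    m = target.matrix
    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        d = k_const * np.where(m > 0, m, np.nan) ** (-1.0 / 3.0)
    finite = np.isfinite(d) & off
    dmax = np.nanmax(d[finite]) if finite.any() else 1.0
    d = np.where(finite, d, 1.5 * dmax)
    np.fill_diagonal(d, 0.0)
    mds = MDS(n_components=3, metric="precomputed", metric_mds=True,
              init="random", normalized_stress=False, n_init=2, max_iter=300,
              random_state=int(seed) % (2 ** 31))
    coords = mds.fit_transform(d)
    s = Structure3D(bins=target.bins.iloc[np.where(target.valid_mask)[0]]
                    .reset_index(drop=True),
                    coordinates=coords, k_const=k_const)
    if min_spearman is not None:
        dd = s.distances
        nz = (m > 0) & off
        rho = spearmanr((k_const / dd[nz]) ** 3, m[nz]).statistic
        if not rho > min_spearman:
            raise EmbeddingError(
                f"embedding round-trip Spearman {rho:.3f} < {min_spearman}")
    return s
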