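"""Gaussian network model of chromatin from Hi-C contact topology.

A contact map ``M`` defines an elastic network on genomic loci through the
Kirchhoff (graph Laplacian) matrix

    Γ_ij = −M_ij            (i ≠ j)
    Γ_ii = Σ_{j≠i} M_ij

whose eigenvectors u_k (mode shapes) and eigenvalues λ_k (squared mode
frequencies, ascending) fully determine the equilibrium fluctuation
statistics: the covariance over the softest m modes is
C = Σ_{k≤m} (1/λ_k) u_k u_kᵀ, its diagonal is the per-locus mean-square
fluctuation (MSF, the "mobility" of a locus), and the correlation cosine
D_ij = C_ij/√(C_ii C_jj) measures directional coupling between loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .errors import ContractError, DegenerateInputError, DisconnectedGraphError
from .hic_io import ContactMap

#: relative threshold below which an eigenvalue is treated as a zero mode
ZERO_EIG_REL_TOL = 1e-10

#: above this size, a sparse shift-invert partial eigensolution is used
DENSE_EIG_CUTOFF = 2500

#: retained mode count default; the softest few hundred modes carry the
#: collective dynamics and keep cross-cell matching affordable
DEFAULT_N_MODES = 500


@dataclass
class Kirchhoff:
    matrix: np.ndarray
    source: ContactMap | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ModeSet:
    """Nonzero eigenpairs of a Kirchhoff matrix, ascending by eigenvalue.

    ``mask`` records which original bins the eigenvector components refer to,
    so mode sets from cells with different dropped regions can be aligned.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_loci, m), columns orthonormal
    n_zero: int = 1
    mask: np.ndarray | None = None
    label: str = ""

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def m(self) -> int:
        return self.eigenvectors.shape[1]

    def truncated(self, m: int) -> "ModeSet":
        m = min(m, self.m)
        return replace(self, eigenvalues=self.eigenvalues[:m],
                       eigenvectors=self.eigenvectors[:, :m])


@dataclass
class Covariance:
    matrix: np.ndarray
    label: str = ""


@dataclass
class MobilityProfile:
    """Per-locus mean-square fluctuation ⟨Δr_i²⟩."""

    msf: np.ndarray
    mask: np.ndarray | None = None
    label: str = ""
    normalized: bool = False


@dataclass
class DirectionalCorrelation:
    matrix: np.ndarray
    label: str = ""


def build_kirchhoff(cm: ContactMap) -> Kirchhoff:
    """Kirchhoff/Laplacian of the contact graph; M's diagonal is ignored
    (a self-contact carries no spring)."""
    m = cm.matrix.copy()
    np.fill_diagonal(m, 0.0)
    gamma = -m
    np.fill_diagonal(gamma, m.sum(axis=1))
    return Kirchhoff(matrix=gamma, source=cm)


def _sign_fix(vecs: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-|component| entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _order_degenerate(vals: np.ndarray, vecs: np.ndarray,
                      rel_gap: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Within a degenerate eigenvalue cluster, order by the index of the
    largest component (overlaps within clusters are basis-dependent)."""
    order = np.arange(len(vals))
    i = 0
    scale = max(abs(vals[-1]), 1.0) if len(vals) else 1.0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[j - 1]) <= rel_gap * scale:
            j += 1
        if j - i > 1:
            peak = np.argmax(np.abs(vecs[:, i:j]), axis=0)
            order[i:j] = order[i:j][np.argsort(peak, kind="stable")]
        i = j
    return vals[order], vecs[:, order]


def decompose(g: Kirchhoff, m: int = DEFAULT_N_MODES, label: str = "",
              mask: np.ndarray | None = None) -> ModeSet:
    """The ``m`` softest nonzero modes of Γ.

    Dense solve for small networks; sparse shift-invert otherwise (a 50-kb
    genome-wide map easily exceeds 5×10⁴ loci). A connected graph has exactly
    one zero mode; more than one raises — callers should filter the map first.
    """
    n = g.n
    if n < 2:
        raise DegenerateInputError("need at least 2 loci")
    if m >= n:
        warnings.warn(f"m={m} clamped to n-1={n - 1}", stacklevel=2)
        m = n - 1
    if n <= DENSE_EIG_CUTOFF:
        vals, vecs = scipy.linalg.eigh(g.matrix)
        lam_max = abs(vals[-1])
    else:
        spars = scipy.sparse.csr_matrix(g.matrix)
        lam_max = float(scipy.sparse.linalg.eigsh(
            spars, k=1, which="LA", return_eigenvectors=False)[0])
        k = min(m + 8, n - 1)
        # small negative shift keeps the factorization nonsingular at λ=0
        vals, vecs = scipy.sparse.linalg.eigsh(
            spars, k=k, sigma=-1e-8 * lam_max, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    tol = ZERO_EIG_REL_TOL * max(lam_max, 1.0)
    n_zero = int(np.sum(vals < tol))
    if n_zero > 1:
        raise DisconnectedGraphError(
            f"{n_zero} zero modes: contact graph has {n_zero} components; "
            "run filter_bins first")
    if n_zero == 0:
        raise ContractError("Laplacian lost its zero mode — invalid input")
    vals = vals[n_zero:n_zero + m]
    vecs = vecs[:, n_zero:n_zero + m]
    vals, vecs = _order_degenerate(vals, vecs)
    vecs = _sign_fix(vecs)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero,
                   mask=np.asarray(mask, dtype=bool) if mask is not None else None,
                   label=label)


def modes_from_map(cm: ContactMap, m: int = DEFAULT_N_MODES,
                   label: str = "") -> ModeSet:
    """Convenience: Kirchhoff + decomposition, carrying the map's mask."""
    ms = decompose(build_kirchhoff(cm), m=m, label=label or cm.provenance,
                   mask=cm.valid_mask)
    return ms


def compute_covariance(modes: ModeSet) -> Covariance:
    """C = Σ_k (1/λ_k) u_k u_kᵀ over the retained modes (pseudoinverse of Γ
    when all n−1 modes are kept)."""
    inv = 1.0 / modes.eigenvalues
    c = (modes.eigenvectors * inv) @ modes.eigenvectors.T
    return Covariance(matrix=c, label=modes.label)


def compute_msf(modes: ModeSet) -> MobilityProfile:
    """MSF_i = Σ_k (1/λ_k) u_ki² — the diagonal of the covariance without
    forming it."""
    msf = ((modes.eigenvectors ** 2) / modes.eigenvalues).sum(axis=1)
    return MobilityProfile(msf=msf, mask=modes.mask, label=modes.label)


def compute_cross_correlation(c: Covariance) -> DirectionalCorrelation:
    """Correlation cosines D_ij = C_ij/√(C_ii C_jj) ∈ [−1, 1]."""
    diag = np.diag(c.matrix)
    if (diag <= 0).any():
        locus = int(np.argmax(diag <= 0))
        raise ContractError(f"zero-variance locus {locus}: C_ii must be > 0")
    d = c.matrix / np.sqrt(np.outer(diag, diag))
    excess = max(d.max() - 1.0, -1.0 - d.min(), 0.0)
    if excess > 1e-9:
        raise ContractError(f"correlation cosine out of [-1,1] by {excess:.2e}")
    return DirectionalCorrelation(matrix=np.clip(d, -1.0, 1.0), label=c.label)


def collectivity(modes: ModeSet) -> np.ndarray:
    """Degree of collectivity κ_k ∈ (0, 1] of each mode.

    Exponential-entropy measure of eigenvector delocalization:
    κ_k = (1/n)·exp(−Σ_i u_ki² ln u_ki²). κ = 1 for a uniformly distributed
    mode, 1/n for a single-locus spike.
    """
    p = modes.eigenvectors ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=0)
    return np.exp(ent) / modes.n


def normalize_profile(p: MobilityProfile) -> MobilityProfile:
    """Scale an MSF profile to unit mean; Pearson correlations between
    profiles are invariant to this scaling."""
    mean = p.msf.mean()
    if mean <= 0:
        raise DegenerateInputError("cannot normalize an all-zero MSF profile")
    return MobilityProfile(msf=p.msf / mean, mask=p.mask, label=p.label,
                           normalized=True)
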