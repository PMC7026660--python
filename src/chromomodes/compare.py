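"""Cross-cell comparison of GNM mode spectra.

Two cells' mode sets are compared through the overlap matrix
[S(A,B)]_kl = |v_k^A · v_l^B| ∈ [0,1]. "Equivalent" modes are found as the
globally cost-minimal injective assignment under cost 1 − S (a rectangular
linear assignment: the reference's first m modes search among the candidate's
first window_factor·m). Whole covariance matrices are compared by the
covariance overlap L(A,B) ∈ [0,1] built from normalized mode variances
w_k = (1/λ_k)/Σ(1/λ_l), and arccos(L) serves as a cell–cell arc distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .errors import AlignmentError, ContractError, DegenerateInputError
from .gnm import MobilityProfile, ModeSet

DEFAULT_WINDOW_FACTOR = 4


@dataclass
class OverlapMatrix:
    entries: np.ndarray  # (m_A, m_B), values in [0, 1]
    label_a: str = ""
    label_b: str = ""


@dataclass
class ModeMatching:
    """Injective assignment of reference mode indices onto candidate indices
    (both 0-based), with the matched overlaps and the total cost Σ(1 − S)."""

    reference: str
    candidate: str
    assignment: np.ndarray  # assignment[k] = candidate index matched to ref mode k
    overlaps: np.ndarray
    total_cost: float


@dataclass
class ConservationProfile:
    """⟨S⟩_k: the diagonal overlap of mode k averaged over all unordered
    cell pairs; `matched` marks profiles taken after mode reassignment."""

    mean_overlap: np.ndarray
    std_overlap: np.ndarray
    n_cells: int
    matched: bool = False


def _align_pair(a: ModeSet, b: ModeSet) -> tuple[np.ndarray, np.ndarray]:
    """Reconcile two mode sets onto their shared valid bins.

    Cells may miss different regions (e.g. centromere bands); eigenvectors are
    restricted to the intersection of valid bins and re-normalized there.
    """
    if a.mask is None and b.mask is None:
        if a.n != b.n:
            raise AlignmentError(
                f"mode sets have {a.n} vs {b.n} loci and no masks to reconcile")
        return a.eigenvectors, b.eigenvectors
    if a.mask is None or b.mask is None or len(a.mask) != len(b.mask):
        raise AlignmentError("masks missing or of different original length")
    if np.array_equal(a.mask, b.mask):
        return a.eigenvectors, b.eigenvectors
    common = a.mask & b.mask
    if common.sum() < 3:
        raise AlignmentError("fewer than 3 shared valid bins")
    va = a.eigenvectors[common[a.mask]]
    vb = b.eigenvectors[common[b.mask]]
    na = np.linalg.norm(va, axis=0)
    nb = np.linalg.norm(vb, axis=0)
    if (na < 1e-12).any() or (nb < 1e-12).any():
        raise AlignmentError("an eigenvector vanishes on the shared bins")
    return va / na, vb / nb


def mode_overlap(a: ModeSet, b: ModeSet) -> OverlapMatrix:
    """[S(A,B)]_kl = |v_k^A · v_l^B| for all retained mode pairs."""
    va, vb = _align_pair(a, b)
    s = np.abs(va.T @ vb)
    return OverlapMatrix(entries=np.minimum(s, 1.0), label_a=a.label,
                         label_b=b.label)


def match_modes(a: ModeSet, b: ModeSet, m: int | None = None,
                window_factor: int = DEFAULT_WINDOW_FACTOR) -> ModeMatching:
    """Cost-minimal injective matching of A's first m modes into B's first
    ``window_factor·m`` modes (Hungarian algorithm on 1 − S)."""
    if m is None:
        m = a.m
    if m > a.m:
        raise AlignmentError(f"m={m} exceeds reference mode count {a.m}")
    window = min(int(window_factor * m), b.m)
    if window < m:
        raise AlignmentError(
            f"candidate window {window} smaller than reference m={m}")
    s = mode_overlap(a.truncated(m), b.truncated(window)).entries
    rows, cols = linear_sum_assignment(1.0 - s)
    order = np.argsort(rows)
    assignment = cols[order]
    overlaps = s[rows[order], assignment]
    return ModeMatching(reference=a.label, candidate=b.label,
                        assignment=assignment, overlaps=overlaps,
                        total_cost=float(np.sum(1.0 - overlaps)))


def reindex_modes(b: ModeSet, matching: ModeMatching) -> ModeSet:
    """Reorder B's modes by a matching so mode k is B's equivalent of the
    reference's mode k. Shapes and frequencies are kept; only indices move."""
    idx = matching.assignment
    return replace(b, eigenvalues=b.eigenvalues[idx],
                   eigenvectors=b.eigenvectors[:, idx])


def conservation_profile(cells: list[ModeSet],
                         matchings: dict[str, ModeMatching] | None = None,
                         m: int | None = None) -> ConservationProfile:
    """Mode conservation ⟨S⟩_k across a cohort.

    Averages the diagonal of S(A,B) over all N(N−1)/2 unordered pairs. When
    ``matchings`` (cell label → matching against a common reference) is given,
    each cell's modes are first reindexed to the reference numbering, so the
    diagonal compares equivalent modes.
    """
    if len(cells) < 2:
        raise DegenerateInputError("need at least two cells")
    if matchings is not None:
        cells = [c if c.label not in matchings else reindex_modes(c, matchings[c.label])
                 for c in cells]
    mm = min(c.m for c in cells)
    if m is not None:
        mm = min(mm, m)
    diags = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            s = mode_overlap(cells[i].truncated(mm), cells[j].truncated(mm))
            diags.append(np.diag(s.entries))
    diags = np.asarray(diags)
    return ConservationProfile(mean_overlap=diags.mean(axis=0),
                               std_overlap=diags.std(axis=0),
                               n_cells=len(cells),
                               matched=matchings is not None)


def mode_weights(modes: ModeSet) -> np.ndarray:
    """Normalized mode variances w_k = (1/λ_k)/Σ_l(1/λ_l); they sum to 1 and
    act as a prior over modes, making cells with different total read counts
    directly comparable."""
    inv = 1.0 / modes.eigenvalues
    return inv / inv.sum()


def covariance_overlap(weights_a: np.ndarray, vecs_a: np.ndarray,
                       weights_b: np.ndarray, vecs_b: np.ndarray) -> float:
    """Covariance overlap L ∈ [0,1] between two weighted mode subspaces.

    L = 1 − sqrt[(Σ(w^A+w^B) − 2ΣΣ √(w_i^A w_j^B)(v_i^A·v_j^B)²) / Σ(w^A+w^B)]
    """
    wa = np.asarray(weights_a, float)
    wb = np.asarray(weights_b, float)
    for w in (wa, wb):
        if abs(w.sum() - 1.0) > 1e-6:
            raise ContractError(f"weights sum to {w.sum():.8f}, expected 1")
    dots2 = (vecs_a.T @ vecs_b) ** 2
    denom = wa.sum() + wb.sum()
    cross = 2.0 * float(np.sqrt(np.outer(wa, wb)).ravel() @ dots2.ravel())
    bracket = (denom - cross) / denom
    if bracket < -1e-9 or bracket > 1.0 + 1e-9:
        raise ContractError(f"covariance-overlap bracket {bracket} outside [0,1]")
    return 1.0 - float(np.sqrt(np.clip(bracket, 0.0, 1.0)))


def covariance_overlap_modesets(a: ModeSet, b: ModeSet,
                                m: int | None = None) -> float:
    """Covariance overlap of two cells' retained mode sets, after mask
    alignment and variance normalization."""
    if m is not None:
        a, b = a.truncated(m), b.truncated(m)
    va, vb = _align_pair(a, b)
    return covariance_overlap(mode_weights(a), va, mode_weights(b), vb)


def covariance_distance(overlap: float) -> float:
    """Arc distance d_cov = arccos(L) ∈ [0, π/2]."""
    if overlap < -1e-9 or overlap > 1.0 + 1e-9:
        raise ContractError(f"covariance overlap {overlap} outside [0,1]")
    return float(np.arccos(np.clip(overlap, 0.0, 1.0)))


def replacement_fraction(matching: ModeMatching, m: int | None = None) -> float:
    """Fraction of the first m reference modes whose equivalent candidate mode
    lies *outside* the candidate's own first m (mode-population change)."""
    if m is None:
        m = len(matching.assignment)
    assigned = matching.assignment[:m]
    return float(np.mean(assigned >= m))


def changed_fraction(matching: ModeMatching, m: int | None = None) -> float:
    """Alternative statistic: fraction of assigned pairs whose candidate index
    differs from the reference index at all."""
    if m is None:
        m = len(matching.assignment)
    assigned = matching.assignment[:m]
    return float(np.mean(assigned != np.arange(m)))


def profile_correlation(p: MobilityProfile, q: MobilityProfile) -> float:
    """Pearson r between two mobility profiles on their shared valid bins."""
    x, y = p.msf, q.msf
    if p.mask is not None and q.mask is not None and not np.array_equal(p.mask, q.mask):
        if len(p.mask) != len(q.mask):
            raise AlignmentError("profiles have different original bin counts")
        common = p.mask & q.mask
        x = x[common[p.mask]]
        y = y[common[q.mask]]
    elif len(x) != len(y):
        raise AlignmentError("profiles have different lengths and no masks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant profile")
    return float(pearsonr(x, y)[0])
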