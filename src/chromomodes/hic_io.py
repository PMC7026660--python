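"""Contact-map containers and I/O.

The canonical interchange format is a sparse triplet TSV (``bin1 bin2 count``,
0-based bin indices, upper or lower triangle or both) with a companion bin
table TSV (``chrom  start  end``, BED-convention half-open intervals). Small
dense TSV matrices are also accepted. Single-cell 3D genome models are
per-locus coordinate tables; they convert to contact maps through the
inverse-cube law ``n = (k/d)^3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateInputError,
    FormatError,
    IncompatibleMapsError,
    SingularityError,
)

SYMMETRY_TOL = 1e-9

BIN_COLUMNS = ["chrom", "start", "end"]


def _validate_bins(bins: pd.DataFrame) -> pd.DataFrame:
    if not set(BIN_COLUMNS) <= set(bins.columns):
        raise FormatError(f"bin table must have columns {BIN_COLUMNS}")
    bins = bins[BIN_COLUMNS].reset_index(drop=True)
    if (bins["start"] >= bins["end"]).any():
        raise FormatError("bin table has start >= end")
    return bins


@dataclass
class ContactMap:
    """A symmetric nonnegative loci-contact matrix with its genomic bin table.

    ``bins`` always describes the *original* binning; ``valid_mask`` marks the
    bins the ``matrix`` currently covers (dropped bins — e.g. unmappable
    centromeric stretches — stay in the table with ``valid_mask`` False so
    results can be re-indexed to original coordinates).
    """

    bin_size: int
    bins: pd.DataFrame
    matrix: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    provenance: str = ""

    def __post_init__(self):
        self.bins = _validate_bins(self.bins)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.bins), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (len(self.bins),):
            raise FormatError("valid_mask length must equal the bin count")
        n = int(self.valid_mask.sum())
        if self.matrix.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} valid bins"
            )
        if self.matrix.size:
            if np.abs(self.matrix - self.matrix.T).max() > SYMMETRY_TOL:
                raise FormatError("contact matrix is asymmetric beyond tolerance")
            if self.matrix.min() < 0:
                raise FormatError("contact matrix has negative entries")

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_bins(self) -> pd.DataFrame:
        return self.bins.loc[self.valid_mask].reset_index(drop=True)

    @property
    def valid_chroms(self) -> np.ndarray:
        return self.bins.loc[self.valid_mask, "chrom"].to_numpy()

    def with_matrix(self, matrix: np.ndarray, provenance: str | None = None) -> "ContactMap":
        return replace(
            self,
            matrix=matrix,
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclass
class Structure3D:
    """Per-locus 3D coordinates of a resolved single-cell genome model."""

    bins: pd.DataFrame
    coordinates: np.ndarray
    k_const: float = 1.0

    def __post_init__(self):
        self.bins = _validate_bins(self.bins)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.bins), 3):
            raise FormatError("coordinates must be (n_bins, 3)")
        if not np.isfinite(self.coordinates).all():
            raise FormatError("coordinates must be finite")

    @property
    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coordinates))


# ---------------------------------------------------------------------------
# readers / writers


def read_bin_table(path: str | Path) -> pd.DataFrame:
    bins = pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=BIN_COLUMNS, dtype={"chrom": str})
    return _validate_bins(bins)


def write_bin_table(bins: pd.DataFrame, path: str | Path) -> None:
    bins[BIN_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def _infer_bin_size(bins: pd.DataFrame) -> int:
    widths = (bins["end"] - bins["start"]).to_numpy()
    return int(np.max(widths))


def read_triplets(matrix_path: str | Path, bins_path: str | Path,
                  bin_size: int | None = None) -> ContactMap:
    """Read the sparse triplet dialect: ``bin1  bin2  count`` plus bin table."""
    bins = read_bin_table(bins_path)
    n = len(bins)
    trip = pd.read_csv(matrix_path, sep="\t", header=None, comment="#",
                       names=["bin1", "bin2", "count"])
    i = trip["bin1"].to_numpy(dtype=int)
    j = trip["bin2"].to_numpy(dtype=int)
    v = trip["count"].to_numpy(dtype=float)
    if len(i) and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
        raise FormatError(f"triplet references a bin outside the {n}-bin table")
    if len(v) and v.min() < 0:
        raise FormatError("negative contact counts")
    m = coo_matrix((v, (i, j)), shape=(n, n)).toarray()
    # mirror whichever triangle(s) were given; explicit conflicts must agree
    upper = np.triu(m, 1)
    lower = np.tril(m, -1)
    both = (upper > 0) & (lower.T > 0)
    if both.any() and np.abs(upper[both] - lower.T[both]).max() > SYMMETRY_TOL:
        raise FormatError("triplets give conflicting values for mirrored pairs")
    off = np.where(upper > 0, upper, lower.T)
    full = off + off.T + np.diag(np.diag(m))
    return ContactMap(
        bin_size=bin_size or _infer_bin_size(bins),
        bins=bins,
        matrix=full,
        provenance=f"triplets:{matrix_path}",
    )


def write_triplets(cm: ContactMap, matrix_path: str | Path,
                   bins_path: str | Path) -> None:
    """Write upper triangle (incl. diagonal) triplets and the bin table.

    Only valid bins are written; the bin table is restricted accordingly so a
    round trip reproduces the analysis-ready map.
    """
    write_bin_table(cm.valid_bins, bins_path)
    iu, ju = np.nonzero(np.triu(cm.matrix))
    pd.DataFrame({"bin1": iu, "bin2": ju, "count": cm.matrix[iu, ju]}).to_csv(
        matrix_path, sep="\t", header=False, index=False)


def read_dense(matrix_path: str | Path, bins_path: str | Path | None = None,
               bin_size: int = 50_000) -> ContactMap:
    m = pd.read_csv(matrix_path, sep="\t", header=None, comment="#").to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise FormatError("dense matrix is not square")
    if np.abs(m - m.T).max() > SYMMETRY_TOL:
        raise FormatError("dense matrix asymmetric beyond tolerance")
    if m.min() < 0:
        raise FormatError("negative contact counts")
    if bins_path is not None:
        bins = read_bin_table(bins_path)
        if len(bins) != m.shape[0]:
            raise FormatError("bin table size does not match matrix")
        bin_size = _infer_bin_size(bins)
    else:
        bins = uniform_bins(m.shape[0], bin_size)
    return ContactMap(bin_size=bin_size, bins=bins, matrix=m,
                      provenance=f"dense:{matrix_path}")


def write_dense(cm: ContactMap, matrix_path: str | Path) -> None:
    pd.DataFrame(cm.matrix).to_csv(matrix_path, sep="\t", header=False, index=False)


def read_contact_map(matrix_path: str | Path, bins_path: str | Path | None = None,
                     format_hint: str | None = None,
                     bin_size: int = 50_000) -> ContactMap:
    """Dispatch to the triplet or dense reader.

    ``format_hint`` may be ``"triplets"`` or ``"dense"``; otherwise the file is
    sniffed (a three-column integer-indexed file is taken as triplets when a
    bin table is supplied).
    """
    path = Path(matrix_path)
    if format_hint is None:
        with open(path) as fh:
            first = fh.readline().split("\t")
        format_hint = "triplets" if (len(first) == 3 and bins_path is not None) else "dense"
    if format_hint == "triplets":
        if bins_path is None:
            raise FormatError("triplet format requires a bin table")
        return read_triplets(path, bins_path, bin_size=None)
    if format_hint == "dense":
        return read_dense(path, bins_path, bin_size=bin_size)
    raise FormatError(f"unknown format hint {format_hint!r}")


def uniform_bins(n_loci: int, bin_size: int,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """A uniform bin table; bins tile each chromosome contiguously."""
    if chrom_sizes is None:
        chrom_sizes = {"chr1": n_loci}
    rows = []
    for chrom, n in chrom_sizes.items():
        for b in range(n):
            rows.append((chrom, b * bin_size, (b + 1) * bin_size))
    bins = pd.DataFrame(rows, columns=BIN_COLUMNS)
    if len(bins) != n_loci:
        raise FormatError("chromosome sizes do not sum to n_loci")
    return bins


def read_structure(path: str | Path, bins_path: str | Path | None = None,
                   bin_size: int = 50_000, k_const: float = 1.0) -> Structure3D:
    """Read a per-locus coordinate TSV (``locus  x  y  z``)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["locus", "x", "y", "z"])
    coords = tab[["x", "y", "z"]].to_numpy(dtype=float)
    bins = read_bin_table(bins_path) if bins_path else uniform_bins(len(tab), bin_size)
    return Structure3D(bins=bins, coordinates=coords, k_const=k_const)


def write_structure(s: Structure3D, path: str | Path) -> None:
    tab = pd.DataFrame(s.coordinates, columns=["x", "y", "z"])
    tab.insert(0, "locus", np.arange(len(tab)))
    tab.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# operations


def _components(matrix: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(matrix), directed=False)
    return labels


def filter_bins(cm: ContactMap, scope: str = "genome") -> ContactMap:
    """Drop contact-free bins and keep the largest connected component.

    ``scope='genome'`` treats the whole map as one graph; ``scope='chromosome'``
    keeps the largest *cis* component of every chromosome independently.
    """
    m = cm.matrix.copy()
    np.fill_diagonal(m, 0.0)
    keep_valid = m.sum(axis=1) > 0
    chroms = cm.valid_chroms
    if scope == "genome":
        sub = m[np.ix_(keep_valid, keep_valid)]
        if sub.shape[0]:
            labels = _components(sub)
            best = np.bincount(labels).argmax()
            idx = np.where(keep_valid)[0][labels == best]
            keep_valid = np.zeros_like(keep_valid)
            keep_valid[idx] = True
    elif scope == "chromosome":
        for chrom in pd.unique(chroms):
            sel = (chroms == chrom) & keep_valid
            if not sel.any():
                continue
            cis = m[np.ix_(sel, sel)]
            labels = _components(cis)
            best = np.bincount(labels).argmax()
            idx = np.where(sel)[0][labels == best]
            drop = sel.copy()
            drop[idx] = False
            keep_valid[drop] = False
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if keep_valid.sum() < 3:
        raise DegenerateInputError(
            f"only {int(keep_valid.sum())} bins survive filtering")
    new_mask = cm.valid_mask.copy()
    new_mask[np.where(cm.valid_mask)[0][~keep_valid]] = False
    return ContactMap(
        bin_size=cm.bin_size,
        bins=cm.bins,
        matrix=cm.matrix[np.ix_(keep_valid, keep_valid)],
        valid_mask=new_mask,
        provenance=f"{cm.provenance}|filter_bins({scope})",
    )


def combine_maps(maps: list[ContactMap]) -> ContactMap:
    """Element-wise sum of contact maps on identical bin tables.

    This is how sparse single-cell maps are pooled into 'combined' data.
    """
    if not maps:
        raise IncompatibleMapsError("no maps to combine")
    first = maps[0]
    for other in maps[1:]:
        if (len(other.bins) != len(first.bins)
                or not other.bins.equals(first.bins)
                or not np.array_equal(other.valid_mask, first.valid_mask)):
            raise IncompatibleMapsError("bin tables / masks differ between maps")
    total = np.sum([m.matrix for m in maps], axis=0)
    prov = "combine[" + ";".join(m.provenance or "?" for m in maps) + "]"
    return first.with_matrix(total, provenance=prov)


def structure_to_contacts(s: Structure3D, cap: float | None = None) -> ContactMap:
    """Convert a 3D model to contact frequencies via ``n = (k/d)^3``.

    No normalization is applied. ``cap`` bounds the frequency for (near-)
    coincident loci; without a cap, a zero distance raises.
    """
    d = s.distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        if cap is None:
            pairs = np.argwhere((d == 0) & off)
            raise SingularityError(
                f"coincident loci (e.g. pair {tuple(pairs[0])}) with no cap configured")
    with np.errstate(divide="ignore"):
        m = (s.k_const / d) ** 3
    np.fill_diagonal(m, 0.0)
    if cap is not None:
        m = np.minimum(m, cap)
    if not np.isfinite(m).all():
        raise SingularityError("nonfinite contact frequencies")
    return ContactMap(
        bin_size=_infer_bin_size(s.bins),
        bins=s.bins,
        matrix=m,
        provenance=f"structure_to_contacts(k={s.k_const})",
    )


def n_connected_components(cm: ContactMap) -> int:
    m = cm.matrix.copy()
    np.fill_diagonal(m, 0.0)
    n_comp, _ = connected_components(csr_matrix(m), directed=False)
    return int(n_comp)
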