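"""Highly-mobile-gene calling and gene-set screening.

A cell's relative mobility at locus i is its MSF minus the cohort-mean MSF.
The top fraction (default 10%) of loci are called highly mobile; genes
overlapping those bins by at least 1 bp are the cell's highly mobile genes
(HMGs). HMG sets are screened against a collection of expression gene sets
(GMT, e.g. highly-expressed-gene lists per cell line) by Jaccard index, and
candidates are rank-ordered per query cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChromomodesError, DegenerateInputError, FormatError
from .gnm import MobilityProfile


@dataclass
class RelativeMobilityProfile:
    """Δ⟨Δr_i²⟩ for one cell against a cohort of size Q; defined on the
    cohort's shared valid bins."""

    cell: str
    delta: np.ndarray
    mask: np.ndarray | None
    cohort_size: int


@dataclass
class GeneAnnotation:
    """BED-convention gene records (0-based, half-open)."""

    records: pd.DataFrame  # columns: gene, chrom, start, end

    def __post_init__(self):
        req = {"gene", "chrom", "start", "end"}
        if not req <= set(self.records.columns):
            raise FormatError(f"annotation needs columns {sorted(req)}")
        r = self.records
        if (r["start"] >= r["end"]).any():
            raise FormatError("gene with start >= end")
        if r["gene"].duplicated().any():
            raise FormatError("duplicate gene ids")


@dataclass
class GeneSet:
    label: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        self.genes = frozenset(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def labels(self) -> list[str]:
        return [s.label for s in self.sets]


@dataclass
class ScreeningResult:
    query: str
    ranking: list[tuple[str, float]]  # (candidate label, Jaccard), descending
    self_rank: int | None = None  # 1-based rank of the query's own label

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["candidate", "jaccard"])


# ---------------------------------------------------------------------------
# BED / GMT I/O


def read_bed(path: str | Path) -> GeneAnnotation:
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "gene"],
                      dtype={"chrom": str, "gene": str})
    return GeneAnnotation(records=tab[["gene", "chrom", "start", "end"]])


def write_bed(ann: GeneAnnotation, path: str | Path) -> None:
    ann.records[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("GMT line needs name, description, >=1 gene")
            sets.append(GeneSet(label=parts[0], description=parts[1],
                                genes=frozenset(parts[2:])))
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll.sets:
            fh.write("\t".join([s.label, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# operations


def relative_mobility(profiles: dict[str, MobilityProfile]
                      ) -> dict[str, RelativeMobilityProfile]:
    """Per-cell MSF minus the cohort mean, on the intersection of valid bins.

    The Δ profiles of the cohort sum to the zero vector by construction.
    """
    if len(profiles) < 2:
        raise DegenerateInputError("relative mobility needs >= 2 cells")
    cells = list(profiles)
    masks = [profiles[c].mask for c in cells]
    if all(m is not None for m in masks):
        lengths = {len(m) for m in masks}
        if len(lengths) != 1:
            raise ChromomodesError("profiles indexed on different binnings")
        common = np.logical_and.reduce(masks)
        values = np.stack([profiles[c].msf[common[profiles[c].mask]] for c in cells])
    else:
        lengths = {len(profiles[c].msf) for c in cells}
        if len(lengths) != 1:
            raise ChromomodesError("profiles of different length without masks")
        common = None
        values = np.stack([profiles[c].msf for c in cells])
    mean = values.mean(axis=0)
    return {
        c: RelativeMobilityProfile(cell=c, delta=values[i] - mean,
                                   mask=common, cohort_size=len(cells))
        for i, c in enumerate(cells)
    }


def call_hm_loci(rel: RelativeMobilityProfile, fraction: float = 0.10,
                 chroms: np.ndarray | None = None,
                 per_chromosome: bool = False) -> set[int]:
    """The ⌈fraction·n⌉ loci of largest relative mobility (highly mobile).

    Returned indices refer to *original* bin coordinates when the profile
    carries a mask. Ties at the threshold are broken by lower bin index.
    By default the quantile is taken over all genome bins jointly; with
    ``per_chromosome`` the top fraction is called within each chromosome
    (``chroms`` gives per-locus chromosome labels on the profile's bins).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(rel.delta)
    positions = np.where(rel.mask)[0] if rel.mask is not None else np.arange(n)

    def top(delta_idx: np.ndarray) -> np.ndarray:
        k = math.ceil(fraction * len(delta_idx))
        order = np.lexsort((delta_idx, -rel.delta[delta_idx]))
        return delta_idx[order[:k]]

    if per_chromosome:
        if chroms is None:
            raise ValueError("per_chromosome calling needs chromosome labels")
        sel = np.concatenate([top(np.where(chroms == c)[0])
                              for c in pd.unique(chroms)])
    else:
        sel = top(np.arange(n))
    return {int(positions[i]) for i in sel}


def loci_to_genes(loci: set[int], ann: GeneAnnotation, bins: pd.DataFrame,
                  label: str = "") -> GeneSet:
    """Genes overlapping any selected bin by >= 1 bp (half-open intervals)."""
    known = set(bins["chrom"].unique())
    sel = bins.iloc[sorted(loci)]
    genes: set[str] = set()
    for _, g in ann.records.iterrows():
        if g["chrom"] not in known:
            warnings.warn(f"gene {g['gene']} on unknown chromosome "
                          f"{g['chrom']}; skipped", stacklevel=2)
            continue
        hits = sel[(sel["chrom"] == g["chrom"])
                   & (sel["start"] < g["end"]) & (g["start"] < sel["end"])]
        if len(hits):
            genes.add(g["gene"])
    return GeneSet(label=label, genes=frozenset(genes),
                   description="highly mobile genes")


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty (keeps rankings total)."""
    union = a.genes | b.genes
    if not union:
        return 0.0
    return len(a.genes & b.genes) / len(union)


def screen(query: GeneSet, collection: GeneSetCollection) -> ScreeningResult:
    """Score every candidate set by Jaccard with the query's HMGs and
    rank-order descending (ties by label)."""
    if not collection.sets:
        raise DegenerateInputError("empty gene-set collection")
    scored = sorted(((s.label, jaccard(query, s)) for s in collection.sets),
                    key=lambda t: (-t[1], t[0]))
    self_rank = None
    for i, (lab, _) in enumerate(scored, start=1):
        if lab == query.label:
            self_rank = i
            break
    return ScreeningResult(query=query.label, ranking=scored,
                           self_rank=self_rank)
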