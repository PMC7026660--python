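"""End-to-end orchestration: simulate → GNM → compare → trees → HMG screen.

A single declarative ``RunConfig`` drives the whole analysis; every output
file is listed in a manifest with SHA-256 checksums so reruns with the same
config and seed can be verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, gnm, hic_io, screen, synthetic, trees
from .errors import ChromomodesError

log = logging.getLogger("chromomodes")


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run.

    Defaults mirror the analysis conventions: 50-kb resolution, the softest
    500 modes, top-10% mobility calls, max aggregation over chromosomes, and
    the first (most stem-like) cell as matching reference.
    """

    outdir: str = "runs/run"
    seed: int = 17
    # synthetic cohort
    n_loci: int = 300
    bin_size: int = 50_000
    n_chromosomes: int = 2
    n_cells: int = 4
    n_tads: int = 6
    decay_exponent: float = 1.0
    intra_tad_boost: float = 4.0
    noise_level: float = 0.1
    perm_block: int = 20
    strength: float = 0.2
    n_hm_loci: int = 10
    # analysis
    n_modes: int = 500
    scope: str = "genome"
    reference: str | None = None
    window_factor: int = 4
    hm_fraction: float = 0.10
    aggregate: str = "max"
    contamination: float = 0.2
    n_decoy_sets: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ChromomodesError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_cohort(config: RunConfig):
    """Synthetic base map + cell family with planted permutations/hm loci."""
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    bounds = tuple(np.linspace(0, n, config.n_tads + 1).astype(int)[1:-1])
    spec = synthetic.SyntheticSpec(
        n_loci=n, bin_size=config.bin_size,
        n_chromosomes=config.n_chromosomes, tad_boundaries=bounds,
        decay_exponent=config.decay_exponent,
        intra_tad_boost=config.intra_tad_boost,
        noise_level=config.noise_level,
        seed=int(rng.integers(2 ** 31)))
    base = synthetic.generate_contact_map(spec)
    perts = []
    all_loci = np.arange(n)
    for c in range(config.n_cells):
        perm = rng.permutation(config.perm_block)
        hm = rng.choice(all_loci, size=config.n_hm_loci, replace=False)
        perts.append(synthetic.PlantedPerturbation(
            mode_permutation=tuple(perm), hm_loci=frozenset(int(i) for i in hm),
            cell_label=f"cell{c:02d}"))
    family = synthetic.generate_cell_family(
        base, perts, strength=config.strength,
        seed=int(rng.integers(2 ** 31)))
    return base, perts, family


def run(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        files.append(path)
        return path

    log.info("stage simulate: %d cells, %d loci", config.n_cells, config.n_loci)
    base, perts, family = build_cohort(config)
    for cm, pert in zip(family, perts):
        hic_io.write_triplets(cm, out / f"{pert.cell_label}.triplets.tsv",
                              out / f"{pert.cell_label}.bins.tsv")
        files += [out / f"{pert.cell_label}.triplets.tsv",
                  out / f"{pert.cell_label}.bins.tsv"]

    log.info("stage gnm: scope=%s, m=%d", config.scope, config.n_modes)
    m_req = config.n_modes
    if m_req >= config.n_loci:
        log.warning("m=%d clamped to n-1=%d", m_req, config.n_loci - 1)
    modesets, profiles = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cm, pert in zip(family, perts):
            ms = gnm.modes_from_map(hic_io.filter_bins(cm, config.scope),
                                    m=m_req, label=pert.cell_label)
            modesets[pert.cell_label] = ms
            profiles[pert.cell_label] = gnm.compute_msf(ms)
    msf_tab = pd.DataFrame({lab: p.msf for lab, p in profiles.items()})
    save_tsv(msf_tab, "msf_profiles.tsv", index_label="locus")

    log.info("stage compare: reference matching and covariance overlaps")
    labels = [p.cell_label for p in perts]
    ref = config.reference or labels[0]
    matchings = {
        lab: compare.match_modes(modesets[ref], modesets[lab],
                                 m=min(config.perm_block * 2,
                                       modesets[ref].m),
                                 window_factor=config.window_factor)
        for lab in labels if lab != ref
    }
    rows = []
    for lab, mt in matchings.items():
        for k, (cand, s) in enumerate(zip(mt.assignment, mt.overlaps)):
            rows.append((ref, lab, k, int(cand), float(s)))
    save_tsv(pd.DataFrame(rows, columns=["reference", "candidate", "ref_mode",
                                         "cand_mode", "overlap"]),
             "matchings.tsv", index=False)
    cons = compare.conservation_profile(list(modesets.values()),
                                        m=config.perm_block * 2)
    cons_m = compare.conservation_profile(list(modesets.values()),
                                          matchings=matchings,
                                          m=config.perm_block * 2)
    save_tsv(pd.DataFrame({"mode": np.arange(1, len(cons.mean_overlap) + 1),
                           "conservation": cons.mean_overlap,
                           "conservation_matched": cons_m.mean_overlap}),
             "conservation.tsv", index=False)

    n_lab = len(labels)
    lmat = np.eye(n_lab)
    for i in range(n_lab):
        for j in range(i + 1, n_lab):
            lmat[i, j] = lmat[j, i] = compare.covariance_overlap_modesets(
                modesets[labels[i]], modesets[labels[j]])
    dmat = np.arccos(np.clip(lmat, 0, 1))
    save_tsv(pd.DataFrame(lmat, index=labels, columns=labels), "cov_overlap.tsv")
    save_tsv(pd.DataFrame(dmat, index=labels, columns=labels), "cov_distance.tsv")

    log.info("stage tree: %s aggregation", config.aggregate)
    graph = trees.build_distance_graph(
        {"all": pd.DataFrame(dmat, index=labels, columns=labels)},
        aggregate=config.aggregate)
    mst = trees.minimum_spanning_tree(graph)
    trees.write_newick(mst, out / "mst.nwk")
    files.append(out / "mst.nwk")
    if n_lab >= 3:
        njt = trees.neighbor_joining(graph)
        trees.write_newick(njt, out / "nj.nwk")
        files.append(out / "nj.nwk")

    log.info("stage hmg: top %.0f%% mobility screen", 100 * config.hm_fraction)
    ann = synthetic.generate_gene_annotation(bins=base.bins,
                                             seed=config.seed + 1)
    rel = screen.relative_mobility(profiles)
    hmg_sets = {}
    for lab in labels:
        loci = screen.call_hm_loci(rel[lab], fraction=config.hm_fraction)
        hmg_sets[lab] = screen.loci_to_genes(loci, ann, base.bins, label=lab)
    true_sets = {p.cell_label: screen.GeneSet(
        label=p.cell_label,
        genes=synthetic.genes_in_bins(ann, base.bins, set(p.hm_loci)))
        for p in perts}
    coll = synthetic.generate_heg_collection(
        true_sets, universe=list(ann.records["gene"]),
        n_decoy_sets=config.n_decoy_sets,
        contamination=config.contamination, seed=config.seed + 2)
    screen.write_gmt(coll, out / "heg_collection.gmt")
    files.append(out / "heg_collection.gmt")
    rows = []
    for lab in labels:
        res = screen.screen(hmg_sets[lab], coll)
        for rank, (cand, j) in enumerate(res.ranking, start=1):
            rows.append((lab, rank, cand, j))
    save_tsv(pd.DataFrame(rows, columns=["query", "rank", "candidate",
                                         "jaccard"]),
             "screening.tsv", index=False)

    manifest = {
        "config": asdict(config),
        "elapsed_s": round(time.time() - t0, 2),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(files))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %d files in %s", len(manifest["files"]), out)
    return manifest
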