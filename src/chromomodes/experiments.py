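"""Planted-truth validation experiments.

Each function runs one self-contained experiment on synthetic data with a
known ground truth — oracle agreement for the covariance solver and the
assignment solver, recovery of planted mode permutations, covariance-overlap
contracts, dendrogram recovery, and the end-to-end highly-mobile-gene screen —
and returns a flat dict of summary statistics. The analysis drivers and the
reproduction script report these numbers; the test suite asserts on them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import compare, gnm, hic_io, screen, synthetic, trees


def _random_connected_map(n: int, rng: np.random.Generator) -> hic_io.ContactMap:
    m = rng.uniform(0, 10, size=(n, n))
    m *= rng.random((n, n)) < 0.3
    m = np.triu(m, 1)
    m = m + m.T
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = rng.uniform(1, 5)
    return hic_io.ContactMap(bin_size=50_000,
                             bins=hic_io.uniform_bins(n, 50_000), matrix=m)


def pseudoinverse_agreement(n_maps: int = 50, max_n: int = 50,
                            seed: int = 0) -> dict:
    """Full-mode covariance vs the Moore–Penrose pseudoinverse of Γ, plus the
    closed-form 3-locus path values (MSF = (5/9, 2/9, 5/9), D₁₂ = −1/√10)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_maps):
        n = int(rng.integers(5, max_n + 1))
        cm = _random_connected_map(n, rng)
        g = gnm.build_kirchhoff(cm)
        ms = gnm.decompose(g, m=n - 1)
        c = gnm.compute_covariance(ms).matrix
        worst = max(worst, float(np.abs(c - np.linalg.pinv(g.matrix)).max()))
    path = hic_io.ContactMap(
        bin_size=1, bins=hic_io.uniform_bins(3, 1),
        matrix=np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float))
    ms = gnm.decompose(gnm.build_kirchhoff(path), m=2)
    msf = gnm.compute_msf(ms).msf
    d = gnm.compute_cross_correlation(gnm.compute_covariance(ms)).matrix
    return {
        "max_pinv_error": worst,
        "n_maps": n_maps,
        "path_msf": msf,
        "path_msf_error": float(np.abs(msf - np.array([5, 2, 5]) / 9).max()),
        "path_d12": float(d[1, 2]),
        "path_d12_error": float(abs(d[1, 2] + 1 / np.sqrt(10))),
    }


def assignment_oracle_agreement(n_trials: int = 200, max_m: int = 7,
                                seed: int = 0) -> dict:
    """Hungarian matching vs exhaustive enumeration over all m! permutations
    on random orthonormal mode sets (square instances, m ≤ 7)."""
    rng = np.random.default_rng(seed)
    agree = 0
    worst_gap = 0.0
    for _ in range(n_trials):
        m = int(rng.integers(2, max_m + 1))
        n = m + int(rng.integers(1, 5))
        a = _random_modeset(n, m, rng)
        b = _random_modeset(n, m, rng)
        mt = compare.match_modes(a, b, m=m, window_factor=1)
        s = compare.mode_overlap(a, b).entries
        best = min(sum(1.0 - s[k, p[k]] for k in range(m))
                   for p in itertools.permutations(range(m)))
        gap = abs(mt.total_cost - best)
        worst_gap = max(worst_gap, gap)
        agree += gap < 1e-10
    return {"agreement_fraction": agree / n_trials, "n_trials": n_trials,
            "worst_cost_gap": worst_gap}


def _random_modeset(n: int, m: int, rng: np.random.Generator) -> gnm.ModeSet:
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    vals = np.sort(rng.uniform(0.5, 5.0, size=m))
    return gnm.ModeSet(eigenvalues=vals, eigenvectors=q[:, :m])


def _permutation_base(n_loci: int = 400, seed: int = 3) -> hic_io.ContactMap:
    # irregular TAD sizes keep the slow spectrum non-degenerate, so planted
    # frequency ranks are well defined
    bounds = tuple(int(round(f * n_loci)) for f in
                   (0.0875, 0.225, 0.325, 0.5125, 0.65, 0.825))
    spec = synthetic.SyntheticSpec(
        n_loci=n_loci, tad_boundaries=bounds, intra_tad_boost=4.0,
        decay_exponent=1.0, noise_level=0.1, seed=seed)
    return synthetic.generate_contact_map(spec)


def permutation_recovery(n_loci: int = 400, k_modes: int = 20,
                         strength: float = 0.3, n_seeds: int = 10,
                         seed: int = 0, m_profile: int = 10) -> dict:
    """Recovery of planted mode-frequency permutations by Hungarian matching,
    and the before- vs after-matching mobility-profile correlation contrast."""
    base = _permutation_base(n_loci, seed=seed + 1)
    ref = gnm.modes_from_map(base, m=5 * k_modes, label="base")
    p_ref = gnm.compute_msf(ref.truncated(m_profile))
    recov, r_before, r_after = [], [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 100 + s)
        perm = tuple(int(x) for x in rng.permutation(k_modes))
        pert = synthetic.PlantedPerturbation(mode_permutation=perm,
                                             cell_label=f"s{s}")
        cell = synthetic.generate_cell_family(base, [pert], strength=strength,
                                              seed=seed + 200 + s)[0]
        ms = gnm.modes_from_map(cell, m=5 * k_modes, label=f"s{s}")
        mt = compare.match_modes(ref, ms, m=k_modes, window_factor=4)
        recov.append(float(np.mean(mt.assignment[:k_modes] == np.array(perm))))
        r_before.append(compare.profile_correlation(
            p_ref, gnm.compute_msf(ms.truncated(m_profile))))
        mt_p = compare.match_modes(ref, ms, m=m_profile, window_factor=4)
        matched = compare.reindex_modes(ms, mt_p)
        r_after.append(compare.profile_correlation(
            p_ref, gnm.compute_msf(matched)))
    return {
        "mean_recovery": float(np.mean(recov)),
        "min_recovery": float(np.min(recov)),
        "mean_r_before": float(np.mean(r_before)),
        "mean_r_after": float(np.mean(r_after)),
        "all_seeds_improved": bool(all(a > b for a, b in
                                       zip(r_after, r_before))),
        "n_seeds": n_seeds,
    }


def covariance_overlap_contract(n_pairs: int = 100, seed: int = 0) -> dict:
    """Identity, symmetry, range and arc-distance contracts of the covariance
    overlap on random mode-set pairs, plus the 45°-rotated single-mode value
    L = 1 − 1/√2."""
    rng = np.random.default_rng(seed)
    max_self_err = max_asym = 0.0
    in_range = True
    max_selfdist = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(4, 16))
        m = int(rng.integers(1, n))
        a = _random_modeset(n, m, rng)
        b = _random_modeset(n, m, rng)
        laa = compare.covariance_overlap_modesets(a, a)
        lab = compare.covariance_overlap_modesets(a, b)
        lba = compare.covariance_overlap_modesets(b, a)
        max_self_err = max(max_self_err, abs(laa - 1.0))
        max_asym = max(max_asym, abs(lab - lba))
        in_range &= 0.0 <= lab <= 1.0
        max_selfdist = max(max_selfdist, compare.covariance_distance(laa))
    e1 = gnm.ModeSet(eigenvalues=np.array([1.0]),
                     eigenvectors=np.array([[1.0], [0.0], [0.0]]))
    diag = gnm.ModeSet(eigenvalues=np.array([1.0]),
                       eigenvectors=np.array([[1 / np.sqrt(2)],
                                              [1 / np.sqrt(2)], [0.0]]))
    l45 = compare.covariance_overlap_modesets(e1, diag)
    return {"max_self_overlap_error": max_self_err,
            "max_asymmetry": max_asym,
            "all_in_unit_interval": in_range,
            "max_self_distance": max_selfdist,
            "worked_L_45deg": l45,
            "worked_L_45deg_error": abs(l45 - (1 - 1 / np.sqrt(2))),
            "n_pairs": n_pairs}


def _tree_distances(edges, leaves):
    import networkx as nx
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    m = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(leaves):
            m[i, j] = lengths[b]
    return m


def _brute_mst_weight(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in seq:
            degree[x] += 1
        edges = []
        deg = list(degree)
        for x in seq:
            leaf = min(i for i in range(n) if deg[i] == 1)
            edges.append((leaf, x))
            deg[leaf] -= 1
            deg[x] -= 1
        last = [i for i in range(n) if deg[i] == 1]
        edges.append((last[0], last[1]))
        best = min(best, sum(matrix[a, b] for a, b in edges))
    return float(best)


def tree_recovery(seed: int = 0, n_seeds: int = 10) -> dict:
    """NJ branch-length recovery on an additive 6-leaf tree, Prim vs
    brute-force MST weight, and bipartition recovery of a planted two-family
    synthetic cohort."""
    edges = [("u", "A", 1.0), ("u", "B", 2.0), ("u", "v", 1.5),
             ("v", "C", 0.5), ("v", "w", 1.0), ("w", "D", 2.5),
             ("w", "E", 0.75), ("u", "F", 3.0)]
    leaves = list("ABCDEF")
    d = _tree_distances(edges, leaves)
    njt = trees.neighbor_joining(trees.DistanceGraph(labels=leaves, matrix=d))
    nj_err = float(np.abs(_tree_distances(njt.edges, leaves) - d).max())

    rng = np.random.default_rng(seed)
    mst_gap = 0.0
    for _ in range(10):
        m = rng.uniform(0.1, 1.0, size=(5, 5))
        m = np.triu(m, 1)
        m = m + m.T
        t = trees.minimum_spanning_tree(
            trees.DistanceGraph(labels=list("ABCDE"), matrix=m))
        mst_gap = max(mst_gap, abs(t.total_weight - _brute_mst_weight(m)))

    ok = 0
    for s in range(n_seeds):
        cells = _two_family_cohort(seed + 300 + s)
        labels = sorted(cells)
        n = len(labels)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                l = compare.covariance_overlap_modesets(cells[labels[i]],
                                                        cells[labels[j]])
                dm[i, j] = dm[j, i] = compare.covariance_distance(l)
        g = trees.build_distance_graph(
            {"all": pd.DataFrame(dm, index=labels, columns=labels)})
        target = frozenset(l for l in labels if l.startswith("B"))
        parts = trees.neighbor_joining(g).bipartitions()
        nj_ok = target in parts or (frozenset(labels) - target) in parts
        mst = trees.minimum_spanning_tree(g)
        cross = sum(1 for a, b, _ in mst.edges if a[0] != b[0])
        ok += nj_ok and cross == 1
    return {"nj_additive_max_error": nj_err,
            "mst_brute_force_max_gap": mst_gap,
            "bipartition_rate": ok / n_seeds,
            "n_seeds": n_seeds}


def _two_family_cohort(seed: int) -> dict[str, gnm.ModeSet]:
    rng = np.random.default_rng(seed)
    spec_a = synthetic.SyntheticSpec(
        n_loci=200, tad_boundaries=(30, 70, 90, 140, 170),
        intra_tad_boost=4.0, noise_level=0.1, seed=seed)
    spec_b = synthetic.SyntheticSpec(
        n_loci=200, tad_boundaries=(20, 55, 105, 130, 160),
        intra_tad_boost=6.0, decay_exponent=1.3, noise_level=0.1,
        seed=seed + 1000)
    cells = {}
    for fam, spec in (("A", spec_a), ("B", spec_b)):
        base = synthetic.generate_contact_map(spec)
        perts = [synthetic.PlantedPerturbation(
            tuple(int(x) for x in rng.permutation(10)),
            cell_label=f"{fam}{k}") for k in range(3)]
        for p, cm in zip(perts, synthetic.generate_cell_family(
                base, perts, strength=0.15, seed=seed + 7)):
            cells[p.cell_label] = gnm.modes_from_map(cm, m=50,
                                                     label=p.cell_label)
    return cells


def hmg_screen_recovery(n_seeds: int = 10, seed: int = 0, n_cells: int = 6,
                        n_loci: int = 300, contamination: float = 0.2,
                        n_decoys: int = 30) -> dict:
    """End-to-end highly-mobile-gene screen: fraction of seeds in which every
    query cell's own expression set ranks first by Jaccard."""
    all_self_first = 0
    self_rank1 = 0
    total = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 500 + s)
        spec = synthetic.SyntheticSpec(
            n_loci=n_loci, n_chromosomes=2,
            tad_boundaries=(40, 80, 120, 180, 210, 270),
            intra_tad_boost=4.0, noise_level=0.1,
            seed=int(rng.integers(2 ** 31)))
        base = synthetic.generate_contact_map(spec)
        perts = []
        for c in range(n_cells):
            perts.append(synthetic.PlantedPerturbation(
                tuple(int(x) for x in rng.permutation(20)),
                hm_loci=frozenset(int(i) for i in
                                  rng.choice(n_loci, 10, replace=False)),
                cell_label=f"cell{c}"))
        fam = synthetic.generate_cell_family(base, perts, strength=0.2,
                                             seed=int(rng.integers(2 ** 31)))
        profiles = {p.cell_label: gnm.compute_msf(
            gnm.modes_from_map(cm, m=100, label=p.cell_label))
            for p, cm in zip(perts, fam)}
        rel = screen.relative_mobility(profiles)
        ann = synthetic.generate_gene_annotation(bins=base.bins,
                                                 seed=int(rng.integers(2 ** 31)))
        hmg, true = {}, {}
        for p in perts:
            loci = screen.call_hm_loci(rel[p.cell_label], 0.10)
            hmg[p.cell_label] = screen.loci_to_genes(loci, ann, base.bins,
                                                     label=p.cell_label)
            true[p.cell_label] = screen.GeneSet(
                p.cell_label,
                synthetic.genes_in_bins(ann, base.bins, set(p.hm_loci)))
        coll = synthetic.generate_heg_collection(
            true, universe=list(ann.records["gene"]), n_decoy_sets=n_decoys,
            contamination=contamination, seed=int(rng.integers(2 ** 31)))
        ranks = [screen.screen(hmg[p.cell_label], coll).self_rank
                 for p in perts]
        self_rank1 += sum(r == 1 for r in ranks)
        total += len(ranks)
        all_self_first += all(r == 1 for r in ranks)
    return {"all_cells_rank1_rate": all_self_first / n_seeds,
            "self_rank1_fraction": self_rank1 / total,
            "n_seeds": n_seeds}


def structural_invariance(seed: int = 0) -> dict:
    """Inverse-cube contact maps from uniformly scaled coordinates share
    identical mode shapes; zero-mode count equals component count."""
    rng = np.random.default_rng(seed)
    coords = rng.standard_normal((40, 3))
    bins = hic_io.uniform_bins(40, 1)
    s1 = hic_io.Structure3D(bins=bins, coordinates=coords, k_const=1.0)
    s2 = hic_io.Structure3D(bins=bins, coordinates=coords * 3.7, k_const=1.0)
    m1 = gnm.modes_from_map(hic_io.structure_to_contacts(s1), m=15)
    m2 = gnm.modes_from_map(hic_io.structure_to_contacts(s2), m=15)
    diag = np.diag(compare.mode_overlap(m1, m2).entries)

    comps_ok = True
    for n_blocks in (2, 3, 4):
        m = np.zeros((6 * n_blocks, 6 * n_blocks))
        for b in range(n_blocks):
            for i in range(6 * b, 6 * b + 5):
                m[i, i + 1] = m[i + 1, i] = 1.0
        import scipy.linalg
        gamma = -m
        np.fill_diagonal(gamma, m.sum(axis=1))
        vals = scipy.linalg.eigvalsh(gamma)
        n_zero = int(np.sum(vals < 1e-10 * max(vals.max(), 1.0)))
        comps_ok &= n_zero == n_blocks
    return {"min_scaled_mode_overlap": float(diag.min()),
            "zero_modes_equal_components": comps_ok}
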