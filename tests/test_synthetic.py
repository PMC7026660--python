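import numpy as np
import pytest
from scipy.stats import spearmanr

from chromomodes import compare, gnm, hic_io, screen, synthetic
from chromomodes.errors import InvalidSpecError
from chromomodes.synthetic import (
    PlantedPerturbation,
    SyntheticSpec,
    expected_contacts,
    generate_cell_family,
    generate_contact_map,
    generate_gene_annotation,
    generate_heg_collection,
    generate_structure,
)


class TestSpecValidation:
    def test_too_few_loci_per_chromosome(self):
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(n_loci=5, n_chromosomes=2)

    def test_boundaries_must_increase(self):
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(n_loci=10, tad_boundaries=(5, 5))
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(n_loci=10, tad_boundaries=(8, 3))
        with pytest.raises(InvalidSpecError):
            SyntheticSpec(n_loci=10, tad_boundaries=(12,))

    def test_permutation_must_be_bijection(self):
        with pytest.raises(InvalidSpecError):
            PlantedPerturbation(mode_permutation=(0, 0, 1))


class TestContactMap:
    def test_noise_free_power_law_closed_form(self):
        spec = SyntheticSpec(n_loci=10, decay_exponent=1.0, amplitude=100.0)
        cm = generate_contact_map(spec)
        i, j = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        lag = np.abs(i - j)
        expected = np.where(lag > 0, 100.0 / np.maximum(lag, 1), 0.0)
        np.testing.assert_allclose(cm.matrix, expected)

    def test_deterministic_under_seed(self):
        spec = SyntheticSpec(n_loci=20, noise_level=0.3, seed=42)
        a = generate_contact_map(spec)
        b = generate_contact_map(spec)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_tad_boost_ratio_matches_generator_expectation(self):
        boost = 3.0
        spec = SyntheticSpec(n_loci=10, tad_boundaries=(5,),
                             intra_tad_boost=boost)
        m = expected_contacts(spec)
        lag2 = [(i, i + 2) for i in range(8)]
        intra = [m[i, j] for i, j in lag2 if (i < 5) == (j < 5)]
        cross = [m[i, j] for i, j in lag2 if (i < 5) != (j < 5)]
        assert np.mean(intra) / np.mean(cross) == pytest.approx(boost)

    def test_generated_maps_pass_validation(self):
        spec = SyntheticSpec(n_loci=40, n_chromosomes=2,
                             tad_boundaries=(8, 25, 33),
                             noise_level=0.2, seed=7)
        cm = generate_contact_map(spec)
        assert np.abs(cm.matrix - cm.matrix.T).max() <= 1e-9
        assert cm.matrix.min() >= 0
        assert hic_io.n_connected_components(cm) == 1
        filtered = hic_io.filter_bins(cm)
        assert filtered.n_valid == 40


def family_base(seed=3, n=120):
    spec = SyntheticSpec(n_loci=n, tad_boundaries=(n // 6, n // 3, n // 2,
                                                   3 * n // 4),
                         intra_tad_boost=4.0, noise_level=0.1, seed=seed)
    return generate_contact_map(spec)


class TestCellFamily:
    def test_identity_perturbation_reproduces_base(self):
        base = family_base()
        pert = PlantedPerturbation(mode_permutation=tuple(range(10)),
                                   cell_label="same")
        out = generate_cell_family(base, [pert], strength=0.0, seed=1)[0]
        np.testing.assert_allclose(out.matrix, base.matrix, atol=1e-8)

    def test_swap_recovered_by_matching(self):
        base = family_base()
        perm = (1, 0) + tuple(range(2, 10))
        pert = PlantedPerturbation(mode_permutation=perm, cell_label="swap")
        out = generate_cell_family(base, [pert], strength=0.1, seed=2)[0]
        a = gnm.modes_from_map(base, m=20, label="base")
        b = gnm.modes_from_map(out, m=20, label="swap")
        mt = compare.match_modes(a, b, m=10, window_factor=2)
        np.testing.assert_array_equal(mt.assignment[:10], perm)

    def test_identity_family_mobility_profiles_nearly_identical(self):
        base = family_base()
        perts = [PlantedPerturbation(tuple(range(5)), cell_label=f"c{i}")
                 for i in range(3)]
        fam = generate_cell_family(base, perts, strength=0.05, seed=3)
        # full-spectrum MSF: truncation would add mode-selection variance on
        # top of the map noise
        profs = [gnm.compute_msf(gnm.modes_from_map(cm, m=119)) for cm in fam]
        for i in range(3):
            for j in range(i + 1, 3):
                assert compare.profile_correlation(profs[i], profs[j]) > 0.99

    def test_planted_mobile_locus_has_top_relative_mobility(self):
        base = family_base()
        perts = [PlantedPerturbation(tuple(range(5)),
                                     hm_loci=frozenset({7}) if i == 0 else frozenset(),
                                     cell_label=f"c{i}")
                 for i in range(3)]
        fam = generate_cell_family(base, perts, strength=0.05, seed=4)
        profiles = {f"c{i}": gnm.compute_msf(gnm.modes_from_map(cm, m=50,
                                                                label=f"c{i}"))
                    for i, cm in enumerate(fam)}
        rel = screen.relative_mobility(profiles)
        assert int(np.argmax(rel["c0"].delta)) == 7

    def test_invalid_strength_rejected(self):
        base = family_base()
        with pytest.raises(InvalidSpecError):
            generate_cell_family(base, [], strength=1.5)


class TestGeneAnnotation:
    def test_one_gene_per_bin(self):
        ann = generate_gene_annotation(n_loci=10, bin_size=100,
                                       genes_per_bin=1, seed=0)
        assert len(ann.records) == 10
        bins = hic_io.uniform_bins(10, 100)
        for b in range(10):
            g = ann.records.iloc[b]
            assert bins.iloc[b]["start"] <= g["start"] < g["end"] <= bins.iloc[b]["end"]

    def test_byte_identical_bed_per_seed(self, tmp_path):
        for trial in ("a", "b"):
            ann = generate_gene_annotation(n_loci=10, bin_size=100, seed=11)
            screen.write_bed(ann, tmp_path / f"{trial}.bed")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()


class TestHegCollection:
    def universe(self, n=200):
        return [f"G{i:06d}" for i in range(n)]

    def test_zero_contamination_self_set_is_top_match(self):
        uni = self.universe()
        hmg = screen.GeneSet("cellA", set(uni[:20]))
        coll = generate_heg_collection({"cellA": hmg}, universe=uni,
                                       n_decoy_sets=0, contamination=0.0,
                                       seed=1)
        assert screen.jaccard(hmg, coll.sets[0]) == pytest.approx(1.0)

    def test_contaminated_set_keeps_stated_fraction(self):
        uni = self.universe()
        hmg = screen.GeneSet("cellA", set(uni[:20]))
        coll = generate_heg_collection({"cellA": hmg}, universe=uni,
                                       n_decoy_sets=0, contamination=0.2,
                                       seed=2)
        heg = coll.sets[0].genes
        assert len(heg) == 20
        assert len(heg & hmg.genes) == 16

    def test_deterministic_gmt(self, tmp_path):
        uni = self.universe()
        hmg = screen.GeneSet("cellA", set(uni[:10]))
        for trial in ("a", "b"):
            coll = generate_heg_collection({"cellA": hmg}, universe=uni,
                                           n_decoy_sets=5, contamination=0.2,
                                           seed=3)
            screen.write_gmt(coll, tmp_path / f"{trial}.gmt")
        assert (tmp_path / "a.gmt").read_bytes() == (tmp_path / "b.gmt").read_bytes()

    def test_contamination_bounds(self):
        with pytest.raises(InvalidSpecError):
            generate_heg_collection({}, universe=self.universe(),
                                    contamination=0.6)


class TestStructure:
    def test_equal_contacts_give_equilateral_triangle(self):
        m = np.ones((3, 3)) - np.eye(3)
        cm = hic_io.ContactMap(bin_size=1, bins=hic_io.uniform_bins(3, 1),
                               matrix=m)
        s = generate_structure(cm, k_const=1.0, seed=0, min_spearman=None)
        d = s.distances
        off = d[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, off[0], rtol=1e-3)

    def test_round_trip_preserves_contact_rank_order(self):
        spec = SyntheticSpec(n_loci=50, tad_boundaries=(15, 35),
                             intra_tad_boost=3.0, seed=5)
        cm = generate_contact_map(spec)
        s = generate_structure(cm, k_const=1.0, seed=6)
        back = hic_io.structure_to_contacts(s)
        nz = cm.matrix > 0
        rho = spearmanr(back.matrix[nz], cm.matrix[nz]).statistic
        assert rho > 0.8

    def test_deterministic_coordinates(self):
        m = np.ones((5, 5)) - np.eye(5)
        cm = hic_io.ContactMap(bin_size=1, bins=hic_io.uniform_bins(5, 1),
                               matrix=m)
        a = generate_structure(cm, seed=9, min_spearman=None)
        b = generate_structure(cm, seed=9, min_spearman=None)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
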