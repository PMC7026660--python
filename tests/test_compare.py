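import itertools

import numpy as np
import pytest
from scipy.stats import ortho_group, spearmanr

from chromomodes import compare, gnm
from chromomodes.compare import (
    changed_fraction,
    conservation_profile,
    covariance_distance,
    covariance_overlap,
    covariance_overlap_modesets,
    match_modes,
    mode_overlap,
    mode_weights,
    profile_correlation,
    reindex_modes,
    replacement_fraction,
)
from chromomodes.errors import AlignmentError, ContractError, DegenerateInputError
from chromomodes.gnm import MobilityProfile, ModeSet

from conftest import random_connected_map


def make_modeset(vecs, eigenvalues=None, label="", mask=None):
    v = np.asarray(vecs, float).T  # rows of `vecs` are modes
    if eigenvalues is None:
        eigenvalues = np.arange(1, v.shape[1] + 1, dtype=float)
    return ModeSet(eigenvalues=np.asarray(eigenvalues, float),
                   eigenvectors=v, label=label, mask=mask)


def random_modeset(n, m, seed, label=""):
    rng = np.random.default_rng(seed)
    q = ortho_group.rvs(n, random_state=rng)[:, :m]
    vals = np.sort(rng.uniform(0.5, 5.0, size=m))
    return ModeSet(eigenvalues=vals, eigenvectors=q, label=label)


class TestModeOverlap:
    def test_self_overlap_is_identity(self):
        a = random_modeset(8, 5, seed=1)
        np.testing.assert_allclose(mode_overlap(a, a).entries, np.eye(5),
                                   atol=1e-10)

    def test_sign_flips_are_immaterial(self):
        a = random_modeset(8, 5, seed=2)
        b = ModeSet(eigenvalues=a.eigenvalues, eigenvectors=-a.eigenvectors)
        np.testing.assert_allclose(mode_overlap(a, b).entries, np.eye(5),
                                   atol=1e-10)

    def test_rotated_mode_overlap_value(self):
        e1 = [1, 0, 0]
        diag = [1 / np.sqrt(2), 1 / np.sqrt(2), 0]
        s = mode_overlap(make_modeset([diag]), make_modeset([e1])).entries
        assert s[0, 0] == pytest.approx(1 / np.sqrt(2))

    def test_mask_reconciliation_renormalizes_on_intersection(self):
        mask_a = np.array([1, 1, 1, 1, 0], bool)
        mask_b = np.array([0, 1, 1, 1, 1], bool)
        va = np.array([0.5, 0.5, 0.5, 0.5])  # on bins 0-3
        vb = np.array([1 / np.sqrt(3)] * 3 + [0.0])  # on bins 1-4
        a = make_modeset([va], mask=mask_a)
        b = make_modeset([vb], mask=mask_b)
        # shared bins 1,2,3: renormalized va = 1/sqrt3 each; vb = 1/sqrt3 each
        s = mode_overlap(a, b).entries
        assert s[0, 0] == pytest.approx(1.0)

    def test_unreconcilable_inputs_raise(self):
        a = make_modeset([[1, 0, 0]])
        b = make_modeset([[1, 0, 0, 0]])
        with pytest.raises(AlignmentError):
            mode_overlap(a, b)


class TestMatchModes:
    def test_swap_recovered(self):
        a = random_modeset(10, 4, seed=3)
        swapped = ModeSet(eigenvalues=a.eigenvalues,
                          eigenvectors=a.eigenvectors[:, [1, 0, 2, 3]])
        mt = match_modes(a, swapped, m=4, window_factor=1)
        np.testing.assert_array_equal(mt.assignment, [1, 0, 2, 3])
        assert mt.total_cost == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("m", [2, 4, 6, 7])
    def test_matches_exhaustive_permutation_oracle(self, m):
        """The Hungarian solution equals the brute-force minimum over all m!
        permutations of the overlap matrix."""
        for seed in range(10):
            a = random_modeset(m + 3, m, seed=100 + seed)
            b = random_modeset(m + 3, m, seed=200 + seed)
            mt = match_modes(a, b, m=m, window_factor=1)
            s = mode_overlap(a, b).entries
            best = min(sum(1 - s[k, p[k]] for k in range(m))
                       for p in itertools.permutations(range(m)))
            assert mt.total_cost == pytest.approx(best, abs=1e-10)

    def test_cost_never_exceeds_identity_assignment(self):
        a = random_modeset(12, 6, seed=5)
        b = random_modeset(12, 6, seed=6)
        mt = match_modes(a, b, m=6, window_factor=1)
        s = mode_overlap(a, b).entries
        assert mt.total_cost <= np.sum(1 - np.diag(s)) + 1e-12

    def test_window_smaller_than_m_raises(self):
        a = random_modeset(10, 6, seed=7)
        b = random_modeset(10, 3, seed=8)
        with pytest.raises(AlignmentError):
            match_modes(a, b, m=6, window_factor=1)

    def test_assignment_injective_within_window(self):
        a = random_modeset(20, 5, seed=9)
        b = random_modeset(20, 19, seed=10)
        mt = match_modes(a, b, m=5, window_factor=4)
        assert len(set(mt.assignment)) == 5
        assert mt.assignment.max() < 19


class TestConservation:
    def test_identical_cells_fully_conserved(self):
        a = random_modeset(10, 6, seed=11)
        cells = [ModeSet(eigenvalues=a.eigenvalues, eigenvectors=a.eigenvectors,
                         label=f"c{i}") for i in range(4)]
        prof = conservation_profile(cells)
        np.testing.assert_allclose(prof.mean_overlap, 1.0, atol=1e-10)

    def test_orthogonal_modes_have_zero_conservation(self):
        a = make_modeset([[1, 0, 0], [0, 1, 0]])
        b = make_modeset([[0, 0, 1], [1, 0, 0]])
        prof = conservation_profile([a, b])
        assert prof.mean_overlap[0] == pytest.approx(0.0)

    def test_averages_over_all_unordered_pairs(self):
        cells = [random_modeset(8, 4, seed=20 + i) for i in range(5)]
        prof = conservation_profile(cells)
        manual = np.mean([np.diag(mode_overlap(a, b).entries)
                          for i, a in enumerate(cells)
                          for b in cells[i + 1:]], axis=0)
        np.testing.assert_allclose(prof.mean_overlap, manual)

    def test_matched_profile_uses_reindexed_diagonal(self):
        ref = random_modeset(10, 4, seed=30, label="ref")
        perm = [2, 0, 3, 1]
        other = ModeSet(eigenvalues=ref.eigenvalues,
                        eigenvectors=ref.eigenvectors[:, np.argsort(perm)],
                        label="other")
        mt = match_modes(ref, other, m=4, window_factor=1)
        prof = conservation_profile([ref, other], matchings={"other": mt})
        np.testing.assert_allclose(prof.mean_overlap, 1.0, atol=1e-10)
        assert prof.matched


class TestCovarianceOverlap:
    def test_self_overlap_is_one(self):
        a = random_modeset(12, 6, seed=40)
        assert covariance_overlap_modesets(a, a) == pytest.approx(1.0)

    def test_orthogonal_single_modes_overlap_zero(self):
        a = make_modeset([[1, 0, 0]], eigenvalues=[1.0])
        b = make_modeset([[0, 1, 0]], eigenvalues=[1.0])
        assert covariance_overlap_modesets(a, b) == pytest.approx(0.0)

    def test_forty_five_degree_single_mode(self):
        a = make_modeset([[1, 0, 0]], eigenvalues=[1.0])
        b = make_modeset([[1 / np.sqrt(2), 1 / np.sqrt(2), 0]],
                         eigenvalues=[1.0])
        assert covariance_overlap_modesets(a, b) == pytest.approx(
            1 - 1 / np.sqrt(2))

    def test_symmetric(self):
        for seed in range(10):
            a = random_modeset(10, 5, seed=seed)
            b = random_modeset(10, 5, seed=seed + 500)
            lab = covariance_overlap_modesets(a, b)
            lba = covariance_overlap_modesets(b, a)
            assert abs(lab - lba) < 1e-10
            assert 0.0 <= lab <= 1.0

    def test_unnormalized_weights_rejected(self):
        v = np.eye(3)[:, :1]
        with pytest.raises(ContractError):
            covariance_overlap(np.array([0.5]), v, np.array([1.0]), v)

    def test_tracks_frobenius_distance_between_covariances(self):
        """1 − L should co-vary with the Frobenius distance between the
        weight-normalized covariance matrices across random pairs."""
        rng = np.random.default_rng(0)
        lvals, fvals = [], []
        for seed in range(40):
            a = random_modeset(8, 7, seed=seed)
            b = random_modeset(8, 7, seed=seed + 1000)
            lvals.append(1 - covariance_overlap_modesets(a, b))
            ca = (a.eigenvectors * mode_weights(a)) @ a.eigenvectors.T
            cb = (b.eigenvectors * mode_weights(b)) @ b.eigenvectors.T
            fvals.append(np.linalg.norm(ca - cb))
        rho = spearmanr(lvals, fvals).statistic
        assert rho > 0

    def test_arc_distance(self):
        assert covariance_distance(1.0) == pytest.approx(0.0)
        assert covariance_distance(0.0) == pytest.approx(np.pi / 2)
        assert covariance_distance(0.5) == pytest.approx(np.pi / 3)
        with pytest.raises(ContractError):
            covariance_distance(1.5)


class TestMatchingStatistics:
    def _matching(self, assignment):
        assignment = np.asarray(assignment)
        return compare.ModeMatching(reference="a", candidate="b",
                                    assignment=assignment,
                                    overlaps=np.ones(len(assignment)),
                                    total_cost=0.0)

    def test_identity_assignment_has_no_replacement(self):
        mt = self._matching(np.arange(10))
        assert replacement_fraction(mt) == 0.0
        assert changed_fraction(mt) == 0.0

    def test_out_of_window_replacements_counted(self):
        assign = np.arange(10)
        assign[3], assign[7] = 10, 14  # two equivalents beyond the first m
        mt = self._matching(assign)
        assert replacement_fraction(mt, m=10) == pytest.approx(0.2)

    def test_changed_fraction_counts_any_reindexing(self):
        mt = self._matching([1, 0, 2, 3])
        assert changed_fraction(mt) == pytest.approx(0.5)
        assert replacement_fraction(mt) == 0.0


class TestProfileCorrelation:
    def test_linear_invariance(self):
        p = MobilityProfile(msf=np.array([1.0, 3.0, 2.0, 5.0]))
        q = MobilityProfile(msf=3.0 * p.msf + 2.0)
        assert profile_correlation(p, p) == pytest.approx(1.0)
        assert profile_correlation(p, q) == pytest.approx(1.0)
        neg = MobilityProfile(msf=-p.msf)
        assert profile_correlation(p, neg) == pytest.approx(-1.0)

    def test_constant_profile_raises(self):
        p = MobilityProfile(msf=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateInputError):
            profile_correlation(p, MobilityProfile(msf=np.ones(3)))

    def test_masked_profiles_use_shared_bins(self):
        mask_p = np.array([1, 1, 1, 0], bool)
        mask_q = np.array([0, 1, 1, 1], bool)
        p = MobilityProfile(msf=np.array([9.0, 1.0, 2.0]), mask=mask_p)
        q = MobilityProfile(msf=np.array([2.0, 4.0, 9.0]), mask=mask_q)
        # shared bins 1,2 -> values (1,2) vs (2,4): perfectly correlated
        assert profile_correlation(p, q) == pytest.approx(1.0)
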