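"""Mantel tests: standard, exact-enumeration and kin-category variants."""

import numpy as np
import pytest

import songkin as sk
from conftest import random_distance_matrix


class TestMantelTest:
    def test_identical_matrices_r_one_min_p(self):
        rng = np.random.default_rng(0)
        a = random_distance_matrix(6, rng)
        res = sk.mantel_test(a, a, n_perm=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == res.p  # defined
        assert res.exact  # n=6 -> 719 < 999 triggers full enumeration
        # identity is the unique maximiser almost surely
        assert res.p <= 2 / 720

    def test_matches_exact_enumeration_n5(self):
        rng = np.random.default_rng(2)
        a = random_distance_matrix(5, rng)
        b = random_distance_matrix(5, rng)
        full = sk.mantel_test(a, b, n_perm=119, seed=0)
        exact = sk.mantel_exact(a, b)
        assert full.p == exact.p
        assert full.r == pytest.approx(exact.r)

    def test_matches_skbio_r(self):
        # independent oracle for the statistic itself
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        a = random_distance_matrix(12, rng)
        b = random_distance_matrix(12, rng)
        res = sk.mantel_test(a, b, n_perm=99, seed=4)
        r_ref, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.values.copy(), a.labels),
            skbio_distance.DistanceMatrix(b.values.copy(), b.labels),
            method="pearson", permutations=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        a = random_distance_matrix(10, rng)
        b = random_distance_matrix(10, rng)
        r1 = sk.mantel_test(a, b, n_perm=99, seed=6).r
        r2 = sk.mantel_test(b, a, n_perm=99, seed=6).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_p_never_zero_and_bounded(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            a = random_distance_matrix(9, rng)
            b = random_distance_matrix(9, rng)
            res = sk.mantel_test(a, b, n_perm=49, seed=seed)
            assert 1 / 50 <= res.p <= 1.0

    def test_quick_type_i_control(self):
        # coarse check; the acceptance suite runs the full calibration
        rng = np.random.default_rng(8)
        rej = 0
        for _ in range(40):
            a = random_distance_matrix(15, rng)
            b = random_distance_matrix(15, rng)
            rej += sk.mantel_test(a, b, n_perm=199, seed=rng).p <= 0.05
        assert rej / 40 <= 0.20

    def test_restriction_consistency(self, dp2_temporal, study_ped, loci):
        # testing a sex-restricted submatrix equals testing pre-restricted
        # matrices: same labels, same statistic, same permutation stream
        _, _, d_ind = dp2_temporal
        gt = sk.simulate_genotypes(study_ped, loci, seed=11)
        gd = sk.relatedness_to_distance(sk.dyadic_ml(gt))
        males = [i for i in d_ind.labels if study_ped[i].sex == "M"]
        r1 = sk.mantel_test(d_ind.submatrix(males), gd.submatrix(males),
                            n_perm=99, seed=12)
        pre_a, pre_b = d_ind.submatrix(males), gd.submatrix(males)
        r2 = sk.mantel_test(pre_a, pre_b, n_perm=99, seed=12)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_errors(self):
        rng = np.random.default_rng(9)
        a = random_distance_matrix(5, rng)
        b = random_distance_matrix(5, rng, labels=[f"y{i}" for i in range(5)])
        with pytest.raises(ValueError, match="label"):
            sk.mantel_test(a, b)
        small = random_distance_matrix(3, rng)
        with pytest.raises(ValueError, match="n >= 4"):
            sk.mantel_test(small, small)
        flat = sk.SquareMatrix(a.labels, np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="variance"):
            sk.mantel_test(flat, a)


class TestMantelExact:
    def test_atom_sizes_n4(self):
        rng = np.random.default_rng(10)
        a = random_distance_matrix(4, rng)
        b = random_distance_matrix(4, rng)
        res = sk.mantel_exact(a, b)
        assert res.p * 24 == pytest.approx(round(res.p * 24))
        assert res.p >= 1 / 24

    def test_identity_pair_minimum_p(self):
        rng = np.random.default_rng(11)
        a = random_distance_matrix(5, rng)
        res = sk.mantel_exact(a, a)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 120

    def test_too_large_n_rejected(self):
        rng = np.random.default_rng(12)
        a = random_distance_matrix(9, rng)
        with pytest.raises(ValueError, match="max_n"):
            sk.mantel_exact(a, a)


class TestKinCategoryMantel:
    def _perfect_design(self, n=7):
        parents = tuple(f"F{i}" for i in range(n))
        offspring = tuple(f"S{i}" for i in range(n))
        labels = parents + offspring
        sim = np.zeros((2 * n, 2 * n))
        for i in range(n):
            sim[i, n + i] = sim[n + i, i] = 1.0
        acoustic = sk.SquareMatrix(labels, sim, diagonal=1.0)
        design = sk.CategoryDesign(parents, offspring, np.eye(n))
        return acoustic, design

    def test_perfect_signal(self):
        acoustic, design = self._perfect_design(7)
        res = sk.kin_category_mantel(acoustic, design, n_perm=999, seed=0,
                                     is_similarity=True)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 5 / 1000

    def test_constant_acoustic_matrix_rejected(self):
        acoustic, design = self._perfect_design(4)
        flat = sk.SquareMatrix(acoustic.labels,
                               np.full((8, 8), 0.5) - 0.5 * np.eye(8))
        with pytest.raises(ValueError, match="variance|degenerate"):
            sk.kin_category_mantel(flat, design, n_perm=99, seed=0)

    def test_too_few_offspring_rejected(self):
        parents = ("F0", "F1")
        design = sk.CategoryDesign(parents, ("S0",), np.array([[1.0], [0.0]]))
        acoustic = sk.SquareMatrix(parents + ("S0",), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="permutation space"):
            sk.kin_category_mantel(acoustic, design, n_perm=9, seed=0)

    def test_design_individual_missing_from_matrix(self):
        acoustic, design = self._perfect_design(4)
        short = acoustic.submatrix(acoustic.labels[:-1])
        with pytest.raises(ValueError, match="missing"):
            sk.kin_category_mantel(short, design, n_perm=9, seed=0)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="exactly one true parent"):
            sk.CategoryDesign(("F0", "F1"), ("S0", "S1"),
                              np.array([[1.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="binary"):
            sk.CategoryDesign(("F0", "F1"), ("S0",),
                              np.array([[0.5], [0.5]]))

    def test_pedigree_design_builder(self, study_ped):
        d = sk.parent_offspring_design(study_ped, "M", "M")
        assert len(d.parents) == 7
        assert len(d.offspring) == 5          # the five sons
        assert d.parent_role == "father" and d.offspring_role == "son"
        d2 = sk.parent_offspring_design(study_ped, "F", "F")
        assert len(d2.offspring) == 4         # the four daughters
        # restricting to present individuals drops orphaned offspring
        present = [i for i in study_ped.ids if i != "G4_M"]
        d3 = sk.parent_offspring_design(study_ped, "M", "M", present=present)
        assert "G4_O1" not in d3.offspring
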