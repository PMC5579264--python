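"""Relatedness estimators, dyad simulation and the comparison harness."""

import numpy as np
import pytest

import songkin as sk
from songkin.pedigree import GenotypeTable
from songkin.relatedness import (RELATEDNESS_CATEGORIES, _dyad_moment,
                                 _ibd_grid, _locus_stats, estimate_dyad_set,
                                 freqs_from_loci)


def _gt(rows, loci=("L1",)):
    """GenotypeTable from {ind: [(a1, a2), ...]} cells."""
    inds = list(rows)
    arr = np.array([rows[i] for i in inds], dtype=int)
    if arr.ndim == 2:
        arr = arr[:, None, :]
    return GenotypeTable(tuple(inds), tuple(loci), arr)


class TestAlleleFrequencies:
    def test_counting_example(self):
        gt = _gt({"x": (1, 1), "y": (1, 2)})
        f = sk.allele_frequencies(gt)["L1"]
        assert f[1] == pytest.approx(0.75)
        assert f[2] == pytest.approx(0.25)

    def test_all_homozygous(self):
        gt = _gt({"x": (1, 1), "y": (1, 1)})
        assert sk.allele_frequencies(gt)["L1"] == {1: 1.0}

    def test_matches_hand_count(self):
        rng = np.random.default_rng(0)
        cells = {f"i{k}": tuple(rng.integers(1, 4, 2)) for k in range(5)}
        f = sk.allele_frequencies(_gt(cells))["L1"]
        flat = [a for cell in cells.values() for a in cell]
        for allele in set(flat):
            assert f[allele] == pytest.approx(flat.count(allele) / len(flat))

    def test_untyped_locus_error(self):
        gt = _gt({"x": (0, 0), "y": (0, 0)})
        with pytest.raises(ValueError, match="no typed"):
            sk.allele_frequencies(gt)


class TestMomentEstimatorFormulas:
    """Frozen single-locus hand evaluations.

    Dyad x = (A, B), y = (A, C) with p = (A: 0.5, B: 0.2, C: 0.3).
    Queller-Goodnight, x reference: num = 0.5*(1+0+0+0) - 0.7 = -0.2,
    den = 1 - 0.7 = 0.3 -> -2/3; y reference: num = 0.5 - 0.8 = -0.3,
    den = 1 - 0.8 = 0.2 -> -3/2; dyad average = -13/12.
    Li: S(AB, AC) = 0.5; S0 = 2*a2 - a3 with a2 = 0.38, a3 = 0.16 -> 0.6;
    r = (0.5 - 0.6)/(1 - 0.6) = -0.25.
    Lynch-Ritland, x ref: num = 0.5*0 + 0.2*1 - 4*0.1 = -0.2,
    den = 1*(0.7) - 0.4 = 0.3 -> -2/3; y ref: num = 0.3 - 0.6 = -0.3,
    den = 0.8 - 0.6 = 0.2 -> -3/2; average = -13/12.
    """

    freqs = {"L1": {1: 0.5, 2: 0.2, 3: 0.3}}
    g1 = np.array([[1, 2]])
    g2 = np.array([[1, 3]])

    @pytest.mark.parametrize("estimator,expected", [
        ("queller_goodnight", -13 / 12),
        ("li", -0.25),
        ("lynch_ritland", -13 / 12),
    ])
    def test_hand_computed_values(self, estimator, expected):
        stats = _locus_stats(self.freqs)
        r = _dyad_moment(self.g1, self.g2, ("L1",), stats, estimator)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_identical_heterozygotes_near_one(self, loci):
        # same fully heterozygous multilocus genotype -> r-hat ~ 1
        g = np.array([[l.alleles[0], l.alleles[1]] for l in loci])
        gt = GenotypeTable(("x", "y"), tuple(l.name for l in loci),
                           np.stack([g, g]))
        freqs = freqs_from_loci(loci)
        for est in ("queller_goodnight", "li", "lynch_ritland", "wang"):
            rm = sk.moment_estimators(gt, freqs, est)
            assert rm.raw[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_wang_category_probabilities_sum_to_one(self, loci):
        for st_ in _locus_stats(freqs_from_loci(loci)).values():
            np.testing.assert_allclose(st_.cat_given_ibd.sum(axis=0),
                                       1.0, atol=1e-12)
            assert np.all(st_.cat_given_ibd >= -1e-12)

    def test_category_probabilities_match_enumeration(self):
        # brute-force enumeration over all ordered genotype pairs under HWE
        from songkin.relatedness import _pair_category
        p = {1: 0.5, 2: 0.3, 3: 0.2}
        st_ = _locus_stats({"L": p})["L"]
        alleles = list(p)
        probs = np.zeros(4)
        for a in alleles:
            for b in alleles:
                for c in alleles:
                    for d in alleles:
                        g1, g2 = tuple(sorted((a, b))), tuple(sorted((c, d)))
                        cat = _pair_category(*g1, *g2)
                        probs[cat] += p[a] * p[b] * p[c] * p[d]
        np.testing.assert_allclose(st_.cat_given_ibd[:, 2], probs, atol=1e-12)


class TestUnbiasedness:
    @pytest.mark.parametrize("category,true_r",
                             sorted(RELATEDNESS_CATEGORIES.items()))
    def test_moment_estimator_means(self, loci, category, true_r):
        # every moment estimator: mean over Mendelian dyads within 3 SE
        dyads = sk.simulate_dyads(loci, category, 400, seed=99)
        for est in ("queller_goodnight", "li", "lynch_ritland", "wang"):
            r = estimate_dyad_set(dyads, est)
            se = np.nanstd(r) / np.sqrt(len(r))
            assert abs(np.nanmean(r) - true_r) < 3 * se + 1e-9, est


class TestDyadicML:
    def test_corner_grid(self, loci):
        # resolution 1 -> only the simplex corners -> r in {0, 0.5, 1}
        dyads = sk.simulate_dyads(loci, "full_sib", 30, seed=5)
        r = estimate_dyad_set(dyads, "dyadic_ml", grid_resolution=1.0)
        assert set(np.round(r, 6)) <= {0.0, 0.5, 1.0}

    def test_grid_points_on_simplex(self):
        g = _ibd_grid(0.1)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert len(g) == 66

    def test_fine_grid_agreement(self, loci):
        dyads = sk.simulate_dyads(loci, "half_sib", 10, seed=6)
        coarse = estimate_dyad_set(dyads, "dyadic_ml", grid_resolution=0.02)
        fine = estimate_dyad_set(dyads, "dyadic_ml", grid_resolution=0.01)
        assert np.all(np.abs(coarse - fine) <= 0.02 + 1e-9)

    def test_parent_offspring_signature_recovers_half(self):
        # 20 loci where the pair always shares exactly one allele and the
        # shared-allele likelihood dominates: ML lands on k1 = 1, r = 0.5
        loci = tuple(sk.LocusSpec.uniform(f"L{i}", (100, 118), 2)
                     for i in range(20))
        g1 = np.array([[100, 102]] * 20)
        g2 = np.array([[100, 104]] * 20)
        gt = GenotypeTable(("p", "o"), tuple(l.name for l in loci),
                           np.stack([g1, g2]))
        rm = sk.dyadic_ml(gt, freqs_from_loci(loci))
        assert rm.raw[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_values_confined_to_unit_interval(self, loci):
        dyads = sk.simulate_dyads(loci, "unrelated", 50, seed=7)
        r = estimate_dyad_set(dyads, "dyadic_ml")
        assert np.all((r >= 0.0) & (r <= 1.0))


class TestSimulateDyads:
    def test_parent_offspring_always_share(self, loci):
        d = sk.simulate_dyads(loci, "parent_offspring", 200, seed=1)
        for i in range(d.n):
            for l in range(len(d.loci)):
                assert np.isin(d.g1[i, l], d.g2[i, l]).any()

    def test_full_sib_category_mixture(self):
        # full sibs share 2/1/0 alleles IBD with probability 1/4, 1/2, 1/4;
        # the observable genotype-pair category frequencies must match the
        # mixture of the exact conditional category probabilities
        locus = sk.LocusSpec.uniform("L", (100, 106), 2)   # 4 alleles
        d = sk.simulate_dyads([locus], "full_sib", 10000, seed=2)
        from songkin.relatedness import _pair_category
        counts = np.zeros(4)
        for i in range(d.n):
            counts[_pair_category(*d.g1[i, 0], *d.g2[i, 0])] += 1
        obs = counts / d.n
        A = _locus_stats(freqs_from_loci([locus]))["L"].cat_given_ibd
        expected = A @ np.array([0.25, 0.5, 0.25])
        np.testing.assert_allclose(obs, expected, atol=0.02)

    def test_unknown_category(self, loci):
        with pytest.raises(ValueError, match="unknown category"):
            sk.simulate_dyads(loci, "cousins", 10, seed=0)

    def test_deterministic(self, loci):
        a = sk.simulate_dyads(loci, "half_sib", 20, seed=3)
        b = sk.simulate_dyads(loci, "half_sib", 20, seed=3)
        np.testing.assert_array_equal(a.g1, b.g1)
        np.testing.assert_array_equal(a.g2, b.g2)


class TestCompareEstimators:
    def test_report_deterministic_and_ranked(self, loci):
        a = sk.compare_estimators(loci, n_per_category=60, seed=4)
        b = sk.compare_estimators(loci, n_per_category=60, seed=4)
        from songkin.relatedness import ALL_ESTIMATORS
        assert a.ranking == b.ranking
        assert a.summary.equals(b.summary)
        assert set(a.ranking) == set(ALL_ESTIMATORS)
        # pooled correlation with truth is meaningfully positive for all
        assert (a.correlations.dropna() > 0.3).all()

    def test_dyadic_ml_correlation_exceeds_half(self, loci):
        rep = sk.compare_estimators(loci, n_per_category=100, seed=8)
        assert rep.correlations["dyadic_ml"] > 0.5

    def test_constant_estimator_flagged_and_ranked_last(self, loci):
        rep = sk.compare_estimators(
            loci, n_per_category=30, seed=9,
            estimators=("queller_goodnight",),
            extra_estimators={"always_zero": lambda d: np.zeros(d.n)})
        assert "always_zero" in rep.degenerate
        assert rep.ranking[-1] == "always_zero"
        assert np.isnan(rep.correlations["always_zero"])

    def test_needs_two_estimators(self, loci):
        with pytest.raises(ValueError, match="two estimators"):
            sk.compare_estimators(loci, 10, seed=0, estimators=("li",))


class TestRelatednessMatrix:
    def test_clamped_export_raw_preserved(self):
        freqs = {"L1": {1: 0.9, 2: 0.1}}
        gt = _gt({"x": (2, 2), "y": (1, 1)})
        rm = sk.moment_estimators(gt, freqs, "queller_goodnight")
        assert rm.raw[0, 1] < -1.0            # moment overshoot
        assert rm.matrix.values[0, 1] == -1.0  # clamped in the export

    def test_pedigree_band_ordering(self, study_ped, loci):
        # medians: unrelated adults < parent-offspring / sibling dyads
        gt = sk.simulate_genotypes(study_ped, loci, seed=42)
        rm = sk.dyadic_ml(gt)
        founders = [i.id for i in study_ped.founders()]
        unrelated = [rm.matrix.values[rm.matrix.index_of(a),
                                      rm.matrix.index_of(b)]
                     for i, a in enumerate(founders)
                     for b in founders[i + 1:]]
        close = []
        for off in study_ped.offspring():
            for parent in (off.father, off.mother):
                close.append(rm.matrix.values[rm.matrix.index_of(off.id),
                                              rm.matrix.index_of(parent)])
        assert np.median(unrelated) < np.median(close)

    def test_distance_conversion_orientation(self, study_ped, loci):
        gt = sk.simulate_genotypes(study_ped, loci, seed=43)
        rm = sk.dyadic_ml(gt)
        dist = sk.relatedness_to_distance(rm)
        off = dist.offdiag()
        assert off.min() == 0.0 and off.max() == 1.0
        # most-related pair maps to distance 0
        i, j = np.unravel_index(
            np.argmax(rm.matrix.values - 10 * np.eye(rm.matrix.n)),
            rm.matrix.values.shape)
        assert dist.values[i, j] == pytest.approx(0.0, abs=1e-12)
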