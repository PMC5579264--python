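"""Linear discriminant and permuted DFA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import songkin as sk
from songkin.features import META_COLUMNS
from songkin.songsim import SongEffectConfig


def _gaussian_classes(rng, means, n_per=30, sd=0.3):
    X, y = [], []
    for k, m in enumerate(means):
        X.append(rng.normal(m, sd, size=(n_per, len(m))))
        y += [f"c{k}"] * n_per
    return np.vstack(X), np.array(y)


class TestLinearDiscriminant:
    def test_separated_classes_perfect_resubstitution(self):
        rng = np.random.default_rng(0)
        X, y = _gaussian_classes(rng, [(0, 0), (5, 5)])
        model = sk.LinearDiscriminant().fit(X, y)
        assert model.score(X, y) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X, y = _gaussian_classes(rng, [(0, 0), (5, 5)])
        accs = []
        for _ in range(50):
            ys = rng.permutation(y)
            accs.append(sk.LinearDiscriminant().fit(X, ys).score(X, ys))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_axis_count_rank_bound(self):
        rng = np.random.default_rng(2)
        X, y = _gaussian_classes(rng, [(0, 0, 0), (3, 0, 0), (0, 3, 0)])
        model = sk.LinearDiscriminant().fit(X, y)
        assert model.axes_.shape[1] == 2        # classes - 1
        X2, y2 = _gaussian_classes(rng, [(0, 0), (4, 4)])
        assert sk.LinearDiscriminant().fit(X2, y2).axes_.shape[1] == 1

    def test_matches_sklearn_predictions(self):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        X, y = _gaussian_classes(rng, [(0, 0, 1), (2, 0, 0), (1, 2, 0)],
                                 n_per=40, sd=0.8)
        Xt = rng.normal(1, 1.5, size=(100, 3))
        ours = sk.LinearDiscriminant().fit(X, y).predict(Xt)
        k = len(np.unique(y))
        ref = sklearn_da.LinearDiscriminantAnalysis(
            priors=np.full(k, 1 / k)).fit(X, y).predict(Xt)
        assert np.mean(ours == ref) > 0.97

    def test_singular_within_scatter_regularized(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        model = sk.LinearDiscriminant().fit(X, y)   # ridge path, no crash
        assert model.score(X, y) == 1.0

    def test_single_case_class_rejected(self):
        with pytest.raises(ValueError, match="single case"):
            sk.LinearDiscriminant().fit(np.zeros((3, 2)),
                                        np.array(["a", "a", "b"]))


def _pdfa_dataset(seed, individual_sd=None, group_sd=None, n_groups=4,
                  kind="temporal"):
    """Small single-type dataset and its PCA scores + metadata."""
    kw = dict(phrase_types=("DP2",), songs_per_group=4, phrases_per_song=2)
    if individual_sd is not None:
        kw["individual_sd"] = {"temporal": individual_sd,
                               "frequency": individual_sd * 300}
        kw["sex_offsets"] = {"temporal": {"M": 0.0, "F": 0.0},
                             "frequency": {"M": 0.0, "F": 0.0}}
    if group_sd is not None:
        kw["group_sd"] = {"temporal": group_sd, "frequency": group_sd * 300}
    rng = np.random.default_rng(seed)
    ped = sk.simulate_pedigree(n_groups, (0, 1), rng)
    phrases = sk.simulate_phrases(ped, SongEffectConfig(**kw), rng)
    ft = sk.feature_table(phrases, kind)
    cols = [c for c in ft.columns if c not in META_COLUMNS]
    pca = sk.pca_kaiser(ft[cols].set_axis(ft["phrase_id"], axis=0))
    return pca.scores, ft[META_COLUMNS].reset_index(drop=True), rng


class TestPdfa:
    def test_deterministic_bitwise(self):
        scores, meta, _ = _pdfa_dataset(0)
        cfg = sk.PDFAConfig(n_selections=5, n_permutations=19, seed=7)
        a = sk.pdfa(scores, meta, cfg)
        b = sk.pdfa(scores, meta, cfg)
        assert (a.training_rate, a.training_p, a.testing_rate, a.testing_p) \
            == (b.training_rate, b.training_p, b.testing_rate, b.testing_p)

    def test_planted_signature_detected(self):
        # strong individual signal: testing rate above chance, p significant
        scores, meta, _ = _pdfa_dataset(1)
        cfg = sk.PDFAConfig(n_selections=10, n_permutations=99,
                            n_selections_null=5, seed=8)
        res = sk.pdfa(scores, meta, cfg)
        assert res.testing_rate > res.chance_rate
        assert res.testing_p <= 0.05
        assert res.training_rate >= res.testing_rate

    def test_no_signal_rate_near_chance(self):
        scores, meta, _ = _pdfa_dataset(2, individual_sd=0.0)
        cfg = sk.PDFAConfig(n_selections=10, n_permutations=19,
                            n_selections_null=2, seed=9)
        res = sk.pdfa(scores, meta, cfg)
        assert abs(res.testing_rate - res.chance_rate) < 15.0

    def test_observed_rates_invariant_to_phrase_shuffling_within_blocks(self):
        scores, meta, _ = _pdfa_dataset(3)
        cfg = sk.PDFAConfig(n_selections=4, n_permutations=5, seed=10)
        a = sk.pdfa(scores, meta, cfg)
        # permute rows only inside each (individual, song) block, so the
        # block structure and block discovery order are untouched
        rng = np.random.default_rng(0)
        perm = np.arange(len(meta))
        blocks = meta.groupby(["individual_id", "song_id"], sort=False).indices
        for idx in blocks.values():
            perm[idx] = rng.permutation(perm[idx])
        b = sk.pdfa(scores.iloc[perm], meta.iloc[perm].reset_index(drop=True),
                    cfg)
        assert a.training_rate == pytest.approx(b.training_rate)
        assert a.testing_rate == pytest.approx(b.testing_rate)

    def test_training_optimism_on_average(self):
        diffs = []
        for seed in range(5):
            scores, meta, _ = _pdfa_dataset(20 + seed)
            cfg = sk.PDFAConfig(n_selections=5, n_permutations=1, seed=seed)
            r = sk.pdfa(scores, meta, cfg)
            diffs.append(r.training_rate - r.testing_rate)
        assert np.mean(diffs) > 0

    def test_single_control_level_error_lists_levels(self):
        scores, meta, _ = _pdfa_dataset(4)
        lone = meta["individual_id"].iloc[0]
        keep = (meta["individual_id"] != lone) | \
               (meta["song_id"] == meta.loc[meta["individual_id"] == lone,
                                            "song_id"].iloc[0])
        with pytest.raises(ValueError, match=str(lone)):
            sk.pdfa(scores[keep.to_numpy()],
                    meta[keep].reset_index(drop=True),
                    sk.PDFAConfig(n_selections=2, n_permutations=2, seed=0))

    def test_quota_must_leave_held_out_blocks(self):
        scores, meta, _ = _pdfa_dataset(5)
        with pytest.raises(ValueError, match="held-out"):
            sk.pdfa(scores, meta,
                    sk.PDFAConfig(n_selections=2, n_permutations=2,
                                  training_quota=4, seed=0))


class TestPdfaBySex:
    def test_single_sex_skipped_with_warning(self):
        scores, meta, _ = _pdfa_dataset(6)
        meta = meta.copy()
        males = meta["sex"] == "M"
        cfg = sk.PDFAConfig(n_selections=3, n_permutations=9, seed=1)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = sk.pdfa_by_sex(scores[males.to_numpy()],
                                 meta[males].reset_index(drop=True), cfg)
        assert list(out) == ["M"]

    def test_equals_prefiltered_run(self):
        scores, meta, _ = _pdfa_dataset(7)
        cfg = sk.PDFAConfig(n_selections=3, n_permutations=9, seed=2)
        by_sex = sk.pdfa_by_sex(scores, meta, cfg)
        males = (meta["sex"] == "M").to_numpy()
        direct = sk.pdfa(scores[males], meta[males].reset_index(drop=True),
                         cfg)
        assert by_sex["M"].testing_rate == direct.testing_rate
        assert by_sex["M"].testing_p == direct.testing_p


class TestPdfaGroup:
    def test_zero_group_effect_usually_not_significant(self):
        # single run; the replicate-level calibration lives in acceptance
        scores, meta, _ = _pdfa_dataset(8, individual_sd=0.08)
        cfg = sk.PDFAConfig(n_selections=5, n_permutations=39,
                            n_selections_null=5, seed=3)
        res = sk.pdfa_group(scores, meta, cfg)
        assert res.chance_rate == pytest.approx(100.0 / meta["group_id"].nunique())

    def test_planted_group_effect_detected(self):
        scores, meta, _ = _pdfa_dataset(9, individual_sd=0.02, group_sd=0.25)
        cfg = sk.PDFAConfig(n_selections=5, n_permutations=99,
                            n_selections_null=5, seed=4)
        res = sk.pdfa_group(scores, meta, cfg)
        assert res.testing_p <= 0.05

    def test_group_with_single_individual_named(self):
        scores, meta, _ = _pdfa_dataset(10)
        meta = meta.copy()
        # orphan one group down to a single individual
        g = meta["group_id"].iloc[0]
        members = meta.loc[meta["group_id"] == g, "individual_id"].unique()
        keep = ~(meta["individual_id"].isin(members[1:])).to_numpy()
        with pytest.raises(ValueError, match="one individual"):
            sk.pdfa_group(scores[keep], meta[keep].reset_index(drop=True),
                          sk.PDFAConfig(n_selections=2, n_permutations=2,
                                        seed=0))
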