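"""Shared fixtures: small synthetic datasets and phrase builders."""

import numpy as np
import pandas as pd
import pytest

import songkin as sk
from songkin.features import META_COLUMNS


def make_unit(start, end, f0_points, q50=None):
    """Unit from (time, f0) pairs."""
    t = np.array([p[0] for p in f0_points], dtype=float)
    f = np.array([p[1] for p in f0_points], dtype=float)
    return sk.Unit(start, end, t, f, q50=q50)


def make_phrase(boundaries, phrase_id="p1", phrase_type=None, q50=None,
                f0=400.0, **meta):
    """Phrase with linear-descent contours from unit (start, end) pairs."""
    if phrase_type is None:
        phrase_type = f"DP{len(boundaries)}"
    units = []
    for (s, e) in boundaries:
        t = np.linspace(s, e, 5)
        f = np.linspace(f0 + 100, f0, 5)
        units.append(sk.Unit(s, e, t, f, q50=q50))
    defaults = dict(individual="ind1", song="s1", group="g1", sex="M")
    defaults.update(meta)
    return sk.PhraseRecord(phrase_id=phrase_id, phrase_type=phrase_type,
                           units=tuple(units), **defaults)


@pytest.fixture(scope="session")
def study_ped():
    return sk.study_pedigree()


@pytest.fixture(scope="session")
def loci():
    return sk.default_loci()


@pytest.fixture(scope="session")
def study_dataset(study_ped, loci):
    """One fixed synthetic dataset: genotypes + phrases (default effects)."""
    gt = sk.simulate_genotypes(study_ped, loci, seed=11)
    phrases = sk.simulate_phrases(study_ped, seed=12)
    return study_ped, gt, phrases


@pytest.fixture(scope="session")
def dp2_temporal(study_dataset):
    """Feature table, PCA and individual distance matrix for DP2 temporal."""
    _, _, phrases = study_dataset
    dp2 = [p for p in phrases if p.phrase_type == "DP2"]
    ft = sk.feature_table(dp2, "temporal")
    cols = [c for c in ft.columns if c not in META_COLUMNS]
    pca = sk.pca_kaiser(ft[cols].set_axis(ft["phrase_id"], axis=0))
    d = sk.phrase_distance(pca.scores)
    mapping = dict(zip(ft["phrase_id"].astype(str),
                       ft["individual_id"].astype(str)))
    d_ind = sk.normalize01(sk.individual_mean_distance(d, mapping))
    return ft, pca, d_ind


def random_distance_matrix(n, rng, labels=None):
    """Euclidean distances between random points (a valid metric matrix)."""
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform
    labels = labels or tuple(f"x{i}" for i in range(n))
    return sk.SquareMatrix(tuple(labels), squareform(pdist(pts)))
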