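"""Distance matrices and Mantel inference: closed-form geometry checks, the
exhaustive-enumeration oracle, and a cross-check against scikit-bio."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qstfst import (
    PairwiseMatrix,
    altitude_diff_matrix,
    geo_distance_matrix,
    linearize_fst,
    log_distance_matrix,
    mantel,
    partial_mantel,
)
from qstfst.matrix_tests import EARTH_RADIUS_KM, DegenerateMatrixError
from qstfst.io_formats import PopulationMetadata
import pandas as pd


def random_matrix(n, rng, labels=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return PairwiseMatrix(labels or [f"p{i}" for i in range(n)], m)


def test_geo_distance_identical_and_antipodal():
    meta = PopulationMetadata(
        pd.DataFrame(
            {
                "population": ["a", "b", "c"],
                "subspecies": ["s"] * 3,
                "latitude": [10.0, 10.0, -10.0],
                "longitude": [20.0, 20.0, -160.0],
                "altitude": [0.0, 0.0, 0.0],
            }
        )
    )
    d = geo_distance_matrix(meta)
    assert d.get("a", "b") == 0.0
    # c is antipodal to a and b
    assert d.get("a", "c") == pytest.approx(math.pi * EARTH_RADIUS_KM, abs=0.01)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.floats(-89, 89), st.floats(-179, 179)),
                min_size=3, max_size=3, unique=True))
def test_geo_distance_triangle_inequality_vs_law_of_cosines(points):
    meta = PopulationMetadata(
        pd.DataFrame(
            {
                "population": ["a", "b", "c"],
                "subspecies": ["s"] * 3,
                "latitude": [p[0] for p in points],
                "longitude": [p[1] for p in points],
                "altitude": [0.0] * 3,
            }
        )
    )
    d = geo_distance_matrix(meta)
    ab, bc, ac = d.get("a", "b"), d.get("b", "c"), d.get("a", "c")
    assert ac <= ab + bc + 1e-6
    # spherical law of cosines as an independent formula
    lat = np.radians([p[0] for p in points])
    lon = np.radians([p[1] for p in points])
    cosang = (
        np.sin(lat[0]) * np.sin(lat[1])
        + np.cos(lat[0]) * np.cos(lat[1]) * np.cos(lon[0] - lon[1])
    )
    expected = EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, cosang)))
    assert ab == pytest.approx(expected, abs=1e-3)


def test_altitude_differences(toy_metadata):
    m = altitude_diff_matrix(toy_metadata)
    assert m.get("p1", "p1") == 0.0
    # 61 m vs 1,564 m differ by 1,503 m
    assert m.get("p1", "p5") == pytest.approx(1503.0)
    assert np.array_equal(m.values, m.values.T)


def test_linearize_fst_values_and_guards():
    m = PairwiseMatrix(
        ["a", "b", "c"],
        np.array([[0.0, 0.5, 0.109], [0.5, 0.0, -0.01], [0.109, -0.01, 0.0]]),
    )
    with pytest.warns(UserWarning, match="clamped"):
        lin = linearize_fst(m)
    assert lin.get("a", "b") == pytest.approx(1.0)
    assert lin.get("a", "c") == pytest.approx(0.109 / 0.891)
    assert lin.get("b", "c") == 0.0
    bad = PairwiseMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        linearize_fst(bad)


def test_log_distance_rejects_zero_distances():
    m = PairwiseMatrix(["a", "b"], np.array([[0.0, 0.0], [0.0, 0.0]]))
    with pytest.raises(ValueError):
        log_distance_matrix(m)
    m2 = PairwiseMatrix(["a", "b"], np.array([[0.0, math.e], [math.e, 0.0]]))
    assert log_distance_matrix(m2).get("a", "b") == pytest.approx(1.0)


def test_mantel_self_correlation_exhaustive():
    rng = np.random.default_rng(2)
    A = random_matrix(5, rng)
    res = mantel(A, A)
    assert res.r == pytest.approx(1.0)
    assert res.method == "exhaustive"
    assert res.n_perm == 120
    # exact proportion of relabelings attaining r = 1
    n_hits = sum(
        1
        for pi in itertools.permutations(range(5))
        if np.corrcoef(
            A.values[np.triu_indices(5, 1)],
            A.values[np.ix_(pi, pi)][np.triu_indices(5, 1)],
        )[0, 1] >= 1.0 - 1e-12
    )
    assert res.p == pytest.approx(n_hits / 120)
    assert res.p >= 1 / 120  # identity always counted


def test_mantel_affine_invariance():
    rng = np.random.default_rng(3)
    A = random_matrix(6, rng)
    vals = 2.5 * A.values + 7.0
    np.fill_diagonal(vals, 0.0)
    B = PairwiseMatrix(list(A.labels), vals)
    assert mantel(A, B).r == pytest.approx(1.0)


def test_mantel_sampled_matches_exhaustive_at_n4():
    rng = np.random.default_rng(4)
    A, B = random_matrix(4, rng), random_matrix(4, rng)
    exact = mantel(A, B)
    assert exact.method == "exhaustive" and exact.n_perm == 24

    # independent sampled estimate of the same null
    iu = np.triu_indices(4, 1)
    r_obs = np.corrcoef(A.values[iu], B.values[iu])[0, 1]
    perm_rng = np.random.default_rng(8)
    hits = 0
    n_perm = 10_000
    for _ in range(n_perm):
        pi = perm_rng.permutation(4)
        r = np.corrcoef(A.values[iu], B.values[np.ix_(pi, pi)][iu])[0, 1]
        hits += r >= r_obs - 1e-12
    sampled_p = (1 + hits) / (n_perm + 1)
    assert sampled_p == pytest.approx(exact.p, abs=0.02)


def test_mantel_label_reordering_invariance():
    rng = np.random.default_rng(6)
    A, B = random_matrix(8, rng), random_matrix(8, rng)
    res = mantel(A, B, n_perm=99, seed=1)
    order = rng.permutation(8)
    labels = [A.labels[i] for i in order]
    res2 = mantel(A.reorder(labels), B.reorder(labels), n_perm=99, seed=1)
    assert res2.r == pytest.approx(res.r, abs=1e-12)


def test_mantel_agrees_with_scikit_bio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(12)
    A, B = random_matrix(8, rng), random_matrix(8, rng)
    ours = mantel(A, B, n_perm=999, seed=5)
    r_sk, p_sk, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(A.values, A.labels),
        skbio_distance.DistanceMatrix(B.values, B.labels),
        method="pearson", permutations=999, alternative="greater",
    )
    assert ours.r == pytest.approx(r_sk, abs=1e-12)
    assert ours.p == pytest.approx(p_sk, abs=0.05)


def test_mantel_guards():
    rng = np.random.default_rng(7)
    A = random_matrix(5, rng)
    const = PairwiseMatrix(list(A.labels), np.ones((5, 5)) - np.eye(5))
    with pytest.raises(DegenerateMatrixError):
        mantel(A, const)
    B = random_matrix(5, rng, labels=["x1", "x2", "x3", "x4", "x5"])
    with pytest.raises(ValueError, match="labels"):
        mantel(A, B)


def test_partial_mantel_reduces_to_mantel_when_control_uncorrelated():
    # build C orthogonal to A and B in the upper triangle
    rng = np.random.default_rng(9)
    A, B = random_matrix(6, rng), random_matrix(6, rng)
    iu = np.triu_indices(6, 1)
    r_ab = np.corrcoef(A.values[iu], B.values[iu])[0, 1]
    # formula check: with the exact r's the statistic matches by construction
    C = random_matrix(6, rng)
    r_ac = np.corrcoef(A.values[iu], C.values[iu])[0, 1]
    r_bc = np.corrcoef(B.values[iu], C.values[iu])[0, 1]
    expected = (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    assert partial_mantel(A, B, C).r == pytest.approx(expected, abs=1e-12)


def test_partial_mantel_identity_and_enumeration_oracle():
    rng = np.random.default_rng(10)
    A = random_matrix(5, rng)
    C = random_matrix(5, rng)
    res = partial_mantel(A, A, C)
    assert res.r == pytest.approx(1.0)

    # brute-force the exhaustive null with independent code
    B = random_matrix(5, rng)
    iu = np.triu_indices(5, 1)
    bv, cv = B.values[iu], C.values[iu]
    r_bc = np.corrcoef(bv, cv)[0, 1]

    def pstat(pi):
        av = A.values[np.ix_(pi, pi)][iu]
        r_ab = np.corrcoef(av, bv)[0, 1]
        r_ac = np.corrcoef(av, cv)[0, 1]
        return (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    obs = pstat(tuple(range(5)))
    stats_all = [pstat(pi) for pi in itertools.permutations(range(5))]
    expected_p = np.mean([s >= obs - 1e-12 for s in stats_all])
    got = partial_mantel(A, B, C)
    assert got.r == pytest.approx(obs, abs=1e-12)
    assert got.p == pytest.approx(expected_p, abs=1e-12)


def test_permutation_p_uniform_under_independence():
    # under independent matrices the one-tailed p is close to uniform
    rng = np.random.default_rng(20)
    ps = []
    for _ in range(200):
        A, B = random_matrix(8, rng), random_matrix(8, rng)
        ps.append(mantel(A, B, n_perm=199, seed=int(rng.integers(2**31))).p)
    from scipy import stats as sps

    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01
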