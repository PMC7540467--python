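"""Distance matrices and Mantel / partial Mantel permutation inference.

The Mantel statistic is the Pearson correlation of the n(n-1)/2 upper-
triangle entries of two symmetric population matrices; its null comes from
simultaneous row/column permutation of one matrix.  For n <= 7 populations
every one of the n! relabelings is enumerated and the p-value is the exact
proportion of permutations at least as extreme (the identity included), so
with five populations the smallest attainable one-tailed p is 1/120.  For
larger n a seeded random sample of permutations is used with the add-one
correction.  The partial Mantel statistic is the first-order partial
correlation of the three pairwise Mantel r's; its null permutes the first
matrix and recomputes the partial statistic.

Geographic distances are great-circle (haversine, Earth radius 6371 km);
isolation by distance is linearized as F/(1-F) against log distance.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from dataclasses import dataclass

from .fst import PairwiseMatrix
from .io_formats import PopulationMetadata

EARTH_RADIUS_KM = 6371.0
EXHAUSTIVE_MAX_N = 7


class DegenerateMatrixError(ValueError):
    """A matrix whose off-diagonal entries carry no variation."""


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str  # greater | less | two-sided
    method: str = "sampled"  # sampled | exhaustive


def geo_distance_matrix(m: PopulationMetadata, populations=None) -> PairwiseMatrix:
    """Great-circle distances (km) between population coordinates."""
    pops = list(populations) if populations is not None else m.populations
    coords = np.radians(m.coordinates(pops))
    if np.any(np.isnan(coords)):
        bad = pops[int(np.where(np.isnan(coords))[0][0])]
        raise ValueError(f"missing coordinates for population {bad!r}")
    lat, lon = coords[:, 0], coords[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(pops, (d + d.T) / 2)


def altitude_diff_matrix(m: PopulationMetadata, populations=None) -> PairwiseMatrix:
    """Absolute altitude differences (m) between populations."""
    pops = list(populations) if populations is not None else m.populations
    alt = m.altitudes(pops)
    return PairwiseMatrix(pops, np.abs(alt[:, None] - alt[None, :]))


def linearize_fst(f: PairwiseMatrix) -> PairwiseMatrix:
    """Entry-wise F/(1-F); negative entries clamped to 0 with a warning."""
    vals = f.values.copy()
    off = ~np.eye(len(f.labels), dtype=bool)
    if np.any(vals[off] >= 1.0):
        raise ValueError("F/(1-F) undefined at F = 1")
    if np.any(vals[off] < 0):
        warnings.warn("negative pairwise F_ST clamped to 0 before linearization")
        vals[off & (vals < 0)] = 0.0
    out = vals / (1.0 - vals)
    np.fill_diagonal(out, 0.0)
    return PairwiseMatrix(list(f.labels), out)


def log_distance_matrix(d: PairwiseMatrix) -> PairwiseMatrix:
    """Companion transform for isolation by distance: log of the distances."""
    vals = d.values.copy()
    off = ~np.eye(len(d.labels), dtype=bool)
    if np.any(vals[off] <= 0):
        raise ValueError("log-distance undefined for zero off-diagonal distances")
    out = np.zeros_like(vals)
    out[off] = np.log(vals[off])
    return PairwiseMatrix(list(d.labels), out)


def _aligned_values(A: PairwiseMatrix, *others: PairwiseMatrix):
    mats = [A.values]
    for B in others:
        if B.labels == A.labels:
            mats.append(B.values)
        elif set(B.labels) == set(A.labels):
            mats.append(B.reorder(A.labels).values)
        else:
            raise ValueError("matrices carry different population labels")
    return mats


def _triu_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise DegenerateMatrixError("constant off-diagonal entries")
    return float(np.corrcoef(x, y)[0, 1])


def _tail_count(stat_perm: np.ndarray, stat_obs: float, tail: str) -> np.ndarray:
    eps = 1e-12
    if tail == "greater":
        return stat_perm >= stat_obs - eps
    if tail == "less":
        return stat_perm <= stat_obs + eps
    if tail == "two-sided":
        return np.abs(stat_perm) >= abs(stat_obs) - eps
    raise ValueError(f"unknown tail {tail!r}")


def _permutation_pvalue(statistic, n: int, stat_obs: float, n_perm: int, seed: int, tail: str):
    """Exact enumeration for small n, else seeded sampling with add-one."""
    if n <= EXHAUSTIVE_MAX_N:
        stats_all = np.array([statistic(np.array(pi)) for pi in itertools.permutations(range(n))])
        p = float(np.mean(_tail_count(stats_all, stat_obs, tail)))
        return p, math.factorial(n), "exhaustive"
    rng = np.random.default_rng(seed)
    stats_perm = np.array([statistic(rng.permutation(n)) for _ in range(n_perm)])
    p = float((1 + np.sum(_tail_count(stats_perm, stat_obs, tail))) / (n_perm + 1))
    return p, n_perm, "sampled"


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel correlation of two population matrices with permutation p."""
    a, b = _aligned_values(A, B)
    n = len(A.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    iu = np.triu_indices(n, k=1)
    r_obs = _triu_corr(a[iu], b[iu])

    def stat(perm: np.ndarray) -> float:
        bp = b[np.ix_(perm, perm)]
        return _triu_corr(a[iu], bp[iu])

    p, n_used, method = _permutation_pvalue(stat, n, r_obs, n_perm, seed, tail)
    return MantelResult(r=r_obs, p=p, n_perm=n_used, tail=tail, method=method)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = (1 - rac**2) * (1 - rbc**2)
    if den <= 0:
        raise DegenerateMatrixError("partial correlation undefined: |r| = 1 with the covariate")
    return (rab - rac * rbc) / math.sqrt(den)


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Partial Mantel r_AB.C with a permutation null on A."""
    a, b, c = _aligned_values(A, B, C)
    n = len(A.labels)
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 populations")
    iu = np.triu_indices(n, k=1)
    av, bv, cv = a[iu], b[iu], c[iu]
    r_bc = _triu_corr(bv, cv)
    r_obs = _partial_r(_triu_corr(av, bv), _triu_corr(av, cv), r_bc)

    def stat(perm: np.ndarray) -> float:
        ap = a[np.ix_(perm, perm)][iu]
        return _partial_r(_triu_corr(ap, bv), _triu_corr(ap, cv), r_bc)

    p, n_used, method = _permutation_pvalue(stat, n, r_obs, n_perm, seed, tail)
    return MantelResult(r=r_obs, p=p, n_perm=n_used, tail=tail, method=method)
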