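"""Neutral genetic differentiation from multi-allelic co-dominant markers.

Implements the Weir & Cockerham (1984) theta estimator: for every locus and
every allele the among-population (a), between-individual-within-population
(b) and within-individual (c) variance components are computed from allele
frequencies, observed heterozygote frequencies and per-population sample
sizes; the multi-locus estimate is the ratio of sums

    theta = sum(a) / sum(a + b + c)

over all loci and alleles.  Monomorphic loci contribute 0/0 and are
skipped.  Missing calls are dropped per locus and individual, so sample
sizes are per-locus.  Significance of the overall estimate comes from
permuting whole individuals (both alleles together) among populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class MonomorphicError(ValueError):
    """All loci monomorphic: theta is 0/0 and undefined."""


@dataclass
class FstEstimate:
    theta: float
    per_locus: dict  # locus -> (a, b, c) summed over alleles
    n_populations: int
    p_value: float | None = None


@dataclass
class PairwiseMatrix:
    """Symmetric population x population matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        vals, tvals = self.values, self.values.T
        both = ~(np.isnan(vals) | np.isnan(tvals))
        if not np.array_equal(np.isnan(vals), np.isnan(tvals)) or not np.array_equal(
            vals[both], tvals[both]
        ):
            raise ValueError("matrix must be symmetric")

    def offdiag(self) -> np.ndarray:
        """Upper-triangle entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def allele_frequencies(g: GenotypeTable, population: str):
    """Per-locus allele frequencies and allele sample sizes for one population.

    Returns ``{locus: ({allele: frequency}, n_alleles_observed)}``.  Loci
    where every call is missing in this population are excluded (logged).
    """
    if population not in g.population_labels:
        raise KeyError(population)
    calls = g.calls[g.populations == population]
    out = {}
    for j, locus in enumerate(g.loci):
        alleles = calls[:, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        if alleles.size == 0:
            logger.warning("locus %s all-missing in population %s; excluded", locus, population)
            continue
        labels, counts = np.unique(alleles, return_counts=True)
        n = int(alleles.size)
        out[locus] = ({int(a): c / n for a, c in zip(labels, counts)}, n)
    return out


def _locus_components(calls: np.ndarray, pop_codes: np.ndarray, n_pops: int):
    """Weir-Cockerham (a, b, c) summed over alleles for one locus.

    ``calls`` is (n, 2) allele codes; returns (a, b, c) or None when the
    locus is monomorphic or observed in fewer than two populations.
    """
    ok = np.all(calls != MISSING, axis=1)
    calls = calls[ok]
    pops = pop_codes[ok]
    alleles = np.unique(calls)
    if alleles.size < 2:
        return None

    # per-population sample sizes (diploid individuals with data)
    n_i = np.bincount(pops, minlength=n_pops).astype(float)
    present = n_i > 0
    r = int(present.sum())
    if r < 2:
        return None
    n_i = n_i[present]
    nbar = n_i.mean()
    n_c = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nbar <= 1 or n_c <= 0:
        return None

    het = calls[:, 0] != calls[:, 1]
    a_sum = b_sum = c_sum = 0.0
    for u in alleles:
        dose = (calls == u).sum(axis=1).astype(float)  # copies of u per individual
        # p_i and heterozygote frequency for allele u, per population
        sum_dose = np.bincount(pops, weights=dose, minlength=n_pops)[present]
        p_i = sum_dose / (2.0 * n_i)
        het_u = het & (dose == 1)
        h_i = np.bincount(pops, weights=het_u.astype(float), minlength=n_pops)[present] / n_i

        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)

        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_fst(g: GenotypeTable, populations=None) -> FstEstimate:
    """Multi-locus Weir-Cockerham theta over a subset of populations."""
    if populations is not None:
        g = g.subset(populations)
    labels = g.population_labels
    if len(labels) < 2:
        raise ValueError("theta needs at least two populations")
    code_of = {p: i for i, p in enumerate(labels)}
    pop_codes = np.asarray([code_of[p] for p in g.populations])

    per_locus = {}
    num = den = 0.0
    for j, locus in enumerate(g.loci):
        comp = _locus_components(g.calls[:, j, :], pop_codes, len(labels))
        if comp is None:
            continue
        per_locus[locus] = comp
        num += comp[0]
        den += comp[0] + comp[1] + comp[2]
    if not per_locus or den == 0.0:
        raise MonomorphicError("all loci monomorphic; theta undefined")
    return FstEstimate(theta=num / den, per_locus=per_locus, n_populations=len(labels))


def pairwise_fst(g: GenotypeTable) -> PairwiseMatrix:
    """Two-population theta for every pair; failures become NaN entries."""
    labels = g.population_labels
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two populations")
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                est = wc_fst(g, [labels[i], labels[j]])
                vals[i, j] = vals[j, i] = est.theta
            except MonomorphicError:
                warnings.warn(f"pair ({labels[i]}, {labels[j]}): theta undefined, set MISSING")
                vals[i, j] = vals[j, i] = np.nan
    return PairwiseMatrix(labels, vals)


def fst_permutation_pvalue(g: GenotypeTable, n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for the overall theta.

    Individuals are shuffled among populations with population sizes held
    fixed; p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    obs = wc_fst(g).theta
    rng = np.random.default_rng(seed)
    count = 0
    perm = GenotypeTable(list(g.individuals), g.populations.copy(), list(g.loci), g.calls)
    for _ in range(n_perm):
        perm.populations = rng.permutation(g.populations)
        try:
            if wc_fst(perm).theta >= obs - 1e-15:
                count += 1
        except MonomorphicError:
            continue
    return (1 + count) / (n_perm + 1)


def gene_diversity(g: GenotypeTable) -> dict:
    """Unbiased expected heterozygosity per locus.

    Within each population Hs = n/(n-1) * (1 - sum p_k^2) with n the number
    of observed allele copies; the locus value averages populations weighted
    by n.  A monomorphic locus scores 0.
    """
    out = {}
    labels = g.population_labels
    for j, locus in enumerate(g.loci):
        num = wtot = 0.0
        for pop in labels:
            alleles = g.calls[g.populations == pop, j, :].ravel()
            alleles = alleles[alleles != MISSING]
            n = alleles.size
            if n < 2:
                continue
            _, counts = np.unique(alleles, return_counts=True)
            p = counts / n
            hs = n / (n - 1) * (1.0 - (p**2).sum())
            num += n * hs
            wtot += n
        if wtot > 0:
            out[locus] = num / wtot
    return out
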