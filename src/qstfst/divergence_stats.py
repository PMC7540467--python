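"""Population and subspecies phenotypic-divergence models.

Per trait and subspecies: a likelihood-ratio test of the population effect
(maximum-likelihood fits of population-as-fixed-effect vs pooled, both with
the container block as a random effect), model-based marginal means per
population, and an ordinary regression of those means on altitude of
origin.  Across subspecies: a sequential Gaussian linear-model partition of
variance into a subspecies term and a population-nested-in-subspecies term
with F tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from ._mixed import MixedModel, indicator_matrix
from .io_formats import PhenotypeTable, PopulationMetadata


@dataclass
class PopulationEffectTest:
    trait: str
    lrt: float
    df: int
    p: float


@dataclass
class MarginalMeans:
    trait: str
    estimates: dict  # population -> (mean, standard error)
    flagged: list = field(default_factory=list)  # populations with < 2 observations


def _ml_block_model(sub: pd.DataFrame, trait: str, X: np.ndarray):
    blk = pd.factorize(sub["block"])[0]
    y = sub[trait].to_numpy(dtype=float)
    return MixedModel(y, X, {"block": indicator_matrix(blk)})


def population_effect_lrt(p: PhenotypeTable, trait: str) -> PopulationEffectTest:
    """LRT of y ~ population + (block) against y ~ 1 + (block), ML fits."""
    sub = p.trait_values(trait)
    pops = pd.factorize(sub["population"])[0]
    k = pops.max() + 1
    if k < 2:
        raise ValueError("need at least two populations")
    full = _ml_block_model(sub, trait, indicator_matrix(pops)).fit("ml")
    null = _ml_block_model(sub, trait, np.ones((len(sub), 1))).fit("ml")
    lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = k - 1
    return PopulationEffectTest(trait=trait, lrt=float(lrt), df=df,
                                p=float(stats.chi2.sf(lrt, df)))


def marginal_means(p: PhenotypeTable, trait: str) -> MarginalMeans:
    """Per-population model-based means with the block effect averaged out.

    The model fits population as a fixed cell-means effect with the block as
    a random effect (REML); estimates are the per-population intercepts with
    their model-based standard errors.
    """
    sub = p.trait_values(trait)
    codes, labels = pd.factorize(sub["population"])
    fit = _ml_block_model(sub, trait, indicator_matrix(codes)).fit("reml")
    se = np.sqrt(np.diag(fit.beta_cov))
    counts = np.bincount(codes)
    flagged = [l for l, c in zip(labels, counts) if c < 2]
    if flagged:
        warnings.warn(f"trait {trait!r}: populations with < 2 observations: {flagged}")
    est = {l: (float(m), float(s)) for l, m, s in zip(labels, fit.beta, se)}
    return MarginalMeans(trait=trait, estimates=est, flagged=flagged)


def altitude_regression(mm: MarginalMeans, m: PopulationMetadata):
    """OLS of population marginal means on altitude; returns (slope, intercept, p)."""
    pops = [pop for pop in mm.estimates if pop in m.populations]
    if len(pops) < 3:
        raise ValueError("altitude regression needs at least 3 populations")
    alt = m.altitudes(pops)
    means = np.array([mm.estimates[pop][0] for pop in pops])
    X = sm.add_constant(alt)
    res = sm.OLS(means, X).fit()
    return float(res.params[1]), float(res.params[0]), float(res.pvalues[1])


def subspecies_partition_r2(p: PhenotypeTable, trait: str):
    """Sequential variance partition: subspecies, then populations within.

    Gaussian linear models with type-I (sequential) sums of squares; returns
    ``(r2_subspecies, p_subspecies, r2_pops_in_subspecies, p_pops)`` where
    each R^2 is that term's share of the total sum of squares and each p is
    the term's F-test probability.
    """
    sub = p.trait_values(trait).rename(columns={trait: "_y"})
    if sub["subspecies"].nunique() < 2:
        raise ValueError("both subspecies must be present")
    model = smf.ols("_y ~ C(subspecies) + C(subspecies):C(population)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_total = table["sum_sq"].sum()
    ss = table["sum_sq"]
    pv = table["PR(>F)"]
    r2_sub = float(ss.iloc[0] / ss_total)
    r2_pop = float(ss.iloc[1] / ss_total)
    return r2_sub, float(pv.iloc[0]), r2_pop, float(pv.iloc[1])
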