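"""Variance components, heritability and Q_ST for a full-sib common garden.

Per trait the random-effects model

    y = mu + population + family(population) + block + residual

is fitted by REML (all effects independent zero-mean Gaussians with
homogeneous variances).  From the components:

* narrow-sense heritability for a full-sib design, h2 = 2 V_w / (V_w + V_res)
  (the family component estimates half the additive variance);
* trait divergence, Q_ST = V_b / (V_b + 2 h2 (V_w + V_res)), which with the
  full-sib h2 reduces algebraically to V_b / (V_b + 4 V_w).

Components whose boundary likelihood-ratio test is nonsignificant can be
treated as null in the downstream formulas.  Confidence intervals come from
a parametric bootstrap: datasets are simulated from the fitted model on the
observed design, refitted, and the statistic's percentile bounds reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import ConvergenceError, DesignError, MixedModel, indicator_matrix
from .fst import PairwiseMatrix
from .io_formats import PhenotypeTable

logger = logging.getLogger(__name__)

COMPONENTS = ("population", "family", "block")


@dataclass
class VarianceComponents:
    V_b: float  # among populations
    V_w: float  # among families within populations
    V_block: float  # among containers
    V_res: float  # residual
    log_likelihood: float
    n_obs: int
    n_pops: int
    n_families: int
    converged: bool = True
    mean: float = 0.0

    def total(self) -> float:
        return self.V_b + self.V_w + self.V_block + self.V_res


@dataclass
class HeritabilityEstimate:
    h2: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0


@dataclass
class QstEstimate:
    qst: float
    trait: str = ""
    scope: str = "overall"
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0


def sqrt_transform(values: np.ndarray) -> np.ndarray:
    """Square-root normalisation; the minimum is shifted to 0 when negative."""
    values = np.asarray(values, dtype=float)
    lo = np.nanmin(values)
    if lo < 0:
        values = values - lo
    return np.sqrt(values)


def _design(p: PhenotypeTable, trait: str, populations=None, transform=None):
    """Listwise-deleted trait vector plus factor codes for the model.

    The response is centred (the offset is returned) so that translation of
    the trait cannot perturb the variance estimates numerically.
    """
    sub = p.trait_values(trait)
    if populations is not None:
        sub = sub[sub["population"].isin(list(populations))].reset_index(drop=True)
    y = sub[trait].to_numpy(dtype=float)
    if transform is not None:
        y = transform(y)
    offset = float(np.mean(y))
    y = y - offset
    pop = pd.factorize(sub["population"])[0]
    fam = pd.factorize(sub["population"] + ":" + sub["family"])[0]
    blk = pd.factorize(sub["block"])[0]
    return y, pop, fam, blk, offset


def _build_model(y, pop, fam, blk, include_block=True, drop=()):
    terms = {}
    if "population" not in drop:
        terms["population"] = indicator_matrix(pop)
    if "family" not in drop:
        terms["family"] = indicator_matrix(fam)
    if include_block and "block" not in drop:
        terms["block"] = indicator_matrix(blk)
    X = np.ones((y.size, 1))
    return MixedModel(y, X, terms)


def _components_from_fit(fit, model, n_pops, n_families, offset=0.0) -> VarianceComponents:
    v = dict(zip(model.term_names, fit.variances))
    return VarianceComponents(
        V_b=float(v.get("population", 0.0)),
        V_w=float(v.get("family", 0.0)),
        V_block=float(v.get("block", 0.0)),
        V_res=float(fit.sigma2),
        log_likelihood=fit.loglik,
        n_obs=fit.n_obs,
        n_pops=n_pops,
        n_families=n_families,
        converged=fit.converged,
        mean=float(fit.beta[0]) + offset,
    )


def fit_variance_components(
    p: PhenotypeTable,
    trait: str,
    populations=None,
    include_block: bool = True,
    transform=None,
) -> VarianceComponents:
    """REML fit of the population/family/block random-effects model."""
    y, pop, fam, blk, offset = _design(p, trait, populations, transform)
    if y.size < 10:
        raise DesignError(f"trait {trait!r}: fewer than 10 non-missing values")
    n_pops = int(pop.max()) + 1
    n_families = int(fam.max()) + 1
    if n_pops < 2:
        raise DesignError("need at least two populations in scope")
    if n_families <= n_pops:
        raise DesignError("need multiple families in some population")
    model = _build_model(y, pop, fam, blk, include_block)
    fit = model.fit("reml")
    if not fit.converged:
        raise ConvergenceError("REML did not converge", fit)
    return _components_from_fit(fit, model, n_pops, n_families, offset)


def test_variance_component(
    p: PhenotypeTable,
    trait: str,
    component: str,
    populations=None,
    alpha: float = 0.05,
    transform=None,
):
    """Boundary LRT for one variance component.

    The full and reduced (component removed) models are fitted by REML with
    the identical fixed part; the statistic 2*(l_full - l_reduced) is
    referred to the 0.5*chi2_0 + 0.5*chi2_1 boundary mixture.  Returns
    ``(lrt, p_value, zeroed)`` with ``zeroed = (p_value >= alpha)``.
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}")
    y, pop, fam, blk, _ = _design(p, trait, populations, transform)
    full = _build_model(y, pop, fam, blk).fit("reml")
    reduced = _build_model(y, pop, fam, blk, drop=(component,)).fit("reml")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < 0:
        if lrt < -1e-4:
            raise ConvergenceError(f"negative LRT {lrt:.3g} beyond tolerance")
        lrt = 0.0
    p_value = 1.0 if lrt == 0.0 else 0.5 * stats.chi2.sf(lrt, df=1)
    return float(lrt), float(p_value), bool(p_value >= alpha)


def apply_zeroing(
    p: PhenotypeTable, trait: str, vc: VarianceComponents, populations=None,
    alpha: float = 0.05, transform=None,
) -> VarianceComponents:
    """Set nonsignificant components (boundary LRT p >= alpha) to null."""
    out = VarianceComponents(**vars(vc))
    for component, attr in (("population", "V_b"), ("family", "V_w"), ("block", "V_block")):
        if getattr(out, attr) == 0.0:
            continue
        _, pval, zeroed = test_variance_component(
            p, trait, component, populations, alpha, transform
        )
        if zeroed:
            logger.info("trait %s: %s variance nonsignificant (p=%.3f), set to 0",
                        trait, component, pval)
            setattr(out, attr, 0.0)
    return out


def heritability_fullsib(vc: VarianceComponents) -> HeritabilityEstimate:
    """h2 = 2 V_w / (V_w + V_res) for full sibs; values > 1 kept, warned."""
    denom = vc.V_w + vc.V_res
    if denom <= 0:
        raise ValueError("V_w + V_res must be positive for heritability")
    h2 = 2.0 * vc.V_w / denom
    if h2 > 1.0:
        warnings.warn(f"full-sib heritability {h2:.3f} exceeds 1; reported as computed")
    return HeritabilityEstimate(h2=float(h2))


def qst_point(vc: VarianceComponents, h2: HeritabilityEstimate, trait: str = "",
              scope: str = "overall") -> QstEstimate:
    """Q_ST = V_b / (V_b + 2 h2 (V_w + V_res))."""
    denom_term = 2.0 * h2.h2 * (vc.V_w + vc.V_res)
    if vc.V_b == 0.0 and denom_term == 0.0:
        raise ValueError("Q_ST undefined: V_b and 2 h2 (V_w + V_res) both zero")
    qst = vc.V_b / (vc.V_b + denom_term)
    return QstEstimate(qst=float(qst), trait=trait, scope=scope)


def pairwise_qst(
    p: PhenotypeTable,
    trait: str,
    h2: HeritabilityEstimate,
    alpha: float = 0.05,
    zeroing: bool = True,
) -> PairwiseMatrix:
    """Population-pairwise Q_ST on the square-root-normalised trait.

    Each pair is refitted on its own data; nonsignificant components are
    treated as null; the shared (subspecies-level) h2 enters every pair.
    Failed fits yield MISSING entries.
    """
    labels = p.populations
    k = len(labels)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = [labels[i], labels[j]]
            try:
                vc = fit_variance_components(p, trait, pair, transform=sqrt_transform)
                if zeroing:
                    vc = apply_zeroing(p, trait, vc, pair, alpha, transform=sqrt_transform)
                q = qst_point(vc, h2, trait, scope=f"{labels[i]}|{labels[j]}").qst
            except (DesignError, ConvergenceError, ValueError) as exc:
                logger.warning("pairwise Q_ST %s-%s failed: %s", labels[i], labels[j], exc)
                q = np.nan
            vals[i, j] = vals[j, i] = q
    return PairwiseMatrix(labels, vals)


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def simulate_from_fit(vc: VarianceComponents, pop, fam, blk, rng) -> np.ndarray:
    """Draw one dataset from the fitted model on the observed design."""
    u = rng.normal(0.0, np.sqrt(vc.V_b), pop.max() + 1)
    v = rng.normal(0.0, np.sqrt(vc.V_w), fam.max() + 1)
    w = rng.normal(0.0, np.sqrt(vc.V_block), blk.max() + 1)
    e = rng.normal(0.0, np.sqrt(vc.V_res), pop.size)
    return vc.mean + u[pop] + v[fam] + w[blk] + e


def bootstrap_components(
    p: PhenotypeTable,
    trait: str,
    n_boot: int,
    seed: int,
    populations=None,
    transform=None,
    vc: VarianceComponents | None = None,
) -> list[VarianceComponents]:
    """Refitted variance components for ``n_boot`` parametric replicates.

    Non-converged replicates are dropped (and logged); a warning is issued
    when more than 10% fail.
    """
    y, pop, fam, blk, offset = _design(p, trait, populations, transform)
    model = _build_model(y, pop, fam, blk)
    if vc is None:
        fit = model.fit("reml")
        vc = _components_from_fit(fit, model, pop.max() + 1, fam.max() + 1, offset)
    rng = np.random.default_rng(seed)
    start = np.array([
        vc.V_b / vc.V_res if vc.V_res > 0 else 0.5,
        vc.V_w / vc.V_res if vc.V_res > 0 else 0.5,
        vc.V_block / vc.V_res if vc.V_res > 0 else 0.5,
    ])
    out: list[VarianceComponents] = []
    failures = 0
    for _ in range(n_boot):
        ystar = simulate_from_fit(vc, pop, fam, blk, rng)
        try:
            fit = model.with_y(ystar).fit("reml", starts=[start, np.full(3, 0.5)])
            out.append(_components_from_fit(fit, model, pop.max() + 1, fam.max() + 1))
        except (ConvergenceError, np.linalg.LinAlgError):
            failures += 1
    if n_boot and failures > 0.1 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed to converge")
    return out


def _statistic_from_components(vc: VarianceComponents, statistic: str) -> float:
    if statistic == "h2":
        return heritability_fullsib(vc).h2
    if statistic == "qst":
        h2 = heritability_fullsib(vc)
        return qst_point(vc, h2).qst
    raise ValueError("statistic must be 'h2' or 'qst'")


def parametric_bootstrap_ci(
    p: PhenotypeTable,
    trait: str,
    statistic: str,
    n_boot: int = 1000,
    seed: int = 0,
    populations=None,
    transform=None,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap bounds for h2 or Q_ST."""
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    comps = bootstrap_components(p, trait, n_boot, seed, populations, transform)
    vals = []
    with warnings.catch_warnings():
        # replicate-level h2 > 1 excursions are expected sampling noise
        warnings.simplefilter("ignore", UserWarning)
        for vc in comps:
            try:
                vals.append(_statistic_from_components(vc, statistic))
            except ValueError:
                continue
    if not vals:
        raise ConvergenceError("no usable bootstrap replicates")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)
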