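"""Q_ST versus F_ST: CI-overlap verdicts and the simulated neutral null.

Two complementary decisions per trait:

* CI overlap — the trait is neutral when the bootstrap CI of the overall
  Q_ST contains the mean F_ST, divergent when F_ST falls below the CI,
  stabilizing when above.

* Simulated neutral null — the observed difference Q_ST - F_ST is referred
  to its distribution under neutral divergence.  Each replicate (i)
  resamples loci with replacement to propagate F_ST estimation error,
  (ii) draws the within-population additive variance V_A = 2 V_w from a
  parametric bootstrap of the family component, which propagates its
  estimation error, (iii) sets the neutral among-population variance to its
  expectation 2 F/(1-F) * V_A, and (iv) *re-estimates* the components from
  the simulated values: the estimated among-population variance is drawn
  through the sampling distributions of the balanced-design mean squares,
  MS_pop ~ chi2 with n_pops - 1 degrees of freedom (finite demes plus
  estimation noise) and MS_fam ~ chi2 with n_families - n_pops degrees of
  freedom.  The replicate records the implied Q_ST minus the resampled
  F_ST; under neutrality the sample is centred near zero and carries the
  same sources of spread as the observed difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fst import FstEstimate
from .io_formats import PhenotypeTable
from .quantgen import QstEstimate, bootstrap_components

F_CLAMP = 1e-6  # floor for resampled F before the 2F/(1-F) scaling


@dataclass
class ComparisonResult:
    trait: str
    qst_obs: float
    fst_mean: float
    diff_obs: float
    p_value: float
    verdict: str  # divergent | stabilizing | neutral
    method: str  # ci_overlap | bootstrap_null
    null_diffs: np.ndarray | None = field(default=None, repr=False)


def ci_overlap_verdict(q: QstEstimate, fst_mean: float) -> ComparisonResult:
    """Verdict from whether the Q_ST bootstrap CI contains the mean F_ST."""
    if not (np.isfinite(q.ci_low) and np.isfinite(q.ci_high)):
        raise ValueError("QstEstimate carries no confidence interval")
    if fst_mean < q.ci_low:
        verdict = "divergent"
    elif fst_mean > q.ci_high:
        verdict = "stabilizing"
    else:
        verdict = "neutral"
    return ComparisonResult(
        trait=q.trait, qst_obs=q.qst, fst_mean=float(fst_mean),
        diff_obs=q.qst - float(fst_mean),
        p_value=np.nan, verdict=verdict, method="ci_overlap",
    )


def va_bootstrap_cache(
    p: PhenotypeTable, trait: str, cache_size: int = 1000, seed: int = 0, populations=None
) -> np.ndarray:
    """Parametric-bootstrap sample of the additive variance V_A = 2 V_w."""
    comps = bootstrap_components(p, trait, cache_size, seed, populations)
    return np.asarray([2.0 * vc.V_w for vc in comps])


def simulate_neutral_diff(
    per_locus_fst: FstEstimate,
    va_cache: np.ndarray,
    vc,
    n_rep: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Neutral-null sample of Q_ST - F_ST.

    ``va_cache`` is the parametric-bootstrap sample of V_A (see
    :func:`va_bootstrap_cache`); it is resampled inside the replicate loop
    instead of refitting the mixed model per replicate, and already carries
    the estimation error of the additive variance.  ``vc`` is the observed
    :class:`~qstfst.quantgen.VarianceComponents` fit: it supplies the design
    sizes (populations, families, observations) and the environmental
    variance used when the components of the simulated values are
    re-estimated through the balanced-design mean-squares distributions.
    Replicates whose resampled F_ST reaches 1 or whose V_A draw is
    non-positive are redrawn; the redraw count is returned alongside the
    sample.
    """
    if n_rep < 1000:
        raise ValueError("n_rep must be at least 1000")
    comps = np.asarray(list(per_locus_fst.per_locus.values()), dtype=float)  # (L, 3)
    if comps.size == 0:
        raise ValueError("per-locus variance components required")
    va_cache = np.asarray(va_cache, dtype=float)
    if va_cache.size == 0:
        raise ValueError("empty V_A cache")
    n_pops, n_families, n_obs = vc.n_pops, vc.n_families, vc.n_obs
    d = n_pops - 1
    fam_df = n_families - n_pops
    res_df = max(n_obs - n_families, 1)
    if d < 1 or fam_df < 1:
        raise ValueError("need at least two populations and nested families")
    s = n_obs / n_families  # sibs per family
    fbar = n_families / n_pops  # families per population
    v_env = vc.V_block + vc.V_res  # environmental variance within families

    rng = np.random.default_rng(seed)
    L = comps.shape[0]
    a = comps[:, 0]
    abc = comps.sum(axis=1)

    diffs = np.empty(n_rep)
    filled = 0
    redrawn = 0
    while filled < n_rep:
        m = n_rep - filled
        idx = rng.integers(0, L, size=(m, L))
        f_sim = a[idx].sum(axis=1) / abc[idx].sum(axis=1)
        f_sim = np.maximum(f_sim, F_CLAMP)  # negative theta is sampling noise
        va = va_cache[rng.integers(0, va_cache.size, size=m)]
        ok = (f_sim < 1.0) & (va > 0.0)
        redrawn += int(m - ok.sum())
        f_ok, va_ok = f_sim[ok], va[ok]
        k = f_ok.size
        # neutral among-population variance given the replicate's V_A, then
        # re-estimation of every component through the sampling
        # distributions of the nested-design mean squares; MS_fam is shared
        # between the V_b and V_A estimates, preserving their negative
        # correlation
        v_b_neutral = 2.0 * f_ok / (1.0 - f_ok) * va_ok
        sigma_fam = v_env + s * (va_ok / 2.0)  # E[MS_fam]
        ms_pop = (sigma_fam + s * fbar * v_b_neutral) * rng.chisquare(d, k) / d
        ms_fam = sigma_fam * rng.chisquare(fam_df, k) / fam_df
        ms_res = v_env * rng.chisquare(res_df, k) / res_df
        v_b_hat = np.maximum((ms_pop - ms_fam) / (s * fbar), 0.0)
        v_a_hat = np.maximum(2.0 * (ms_fam - ms_res) / s, 0.0)
        denom = v_b_hat + 2.0 * v_a_hat
        q_sim = np.divide(v_b_hat, denom, out=np.zeros(k), where=denom > 0)
        diffs[filled : filled + k] = q_sim - f_ok
        filled += k
    return diffs, redrawn


def bootstrap_null_pvalue(
    diff_obs: float,
    null_diffs: np.ndarray,
    trait: str = "",
    qst_obs: float = np.nan,
    fst_mean: float = np.nan,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed add-one permutation-style p for the observed difference."""
    null_diffs = np.asarray(null_diffs, dtype=float)
    if null_diffs.size == 0:
        raise ValueError("empty null sample")
    n = null_diffs.size
    upper = (1 + np.sum(null_diffs >= diff_obs)) / (n + 1)
    lower = (1 + np.sum(null_diffs <= diff_obs)) / (n + 1)
    p = min(1.0, 2.0 * min(upper, lower))
    if p < alpha:
        verdict = "divergent" if diff_obs > 0 else "stabilizing"
    else:
        verdict = "neutral"
    return ComparisonResult(
        trait=trait, qst_obs=qst_obs, fst_mean=fst_mean,
        diff_obs=float(diff_obs),
        p_value=float(p), verdict=verdict, method="bootstrap_null",
        null_diffs=null_diffs,
    )
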