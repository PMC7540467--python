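"""Simulation experiments validating the pipeline under its study conditions.

Each experiment regenerates data with the synthetic-data module at the
design scale of the target study, runs the estimator under test, and
returns a summary number together with the problem size used:

* theta recovery on Balding-Nichols panels at the study's differentiation;
* Q_ST recovery at the common-garden design scale for a known true Q_ST;
* REML versus the balanced nested-ANOVA closed form;
* type-I error of the neutral-null (Whitlock-Guillaume style) comparison
  under fully neutral end-to-end simulation;
* sampled versus exhaustively enumerated Mantel p-values;
* coverage of the parametric-bootstrap CI for heritability.

Replicate counts are sized for a desk-scale run of a few minutes each; they
are parameters, so larger studies are one argument away.
"""

from __future__ import annotations

import numpy as np

from .compare import bootstrap_null_pvalue, simulate_neutral_diff
from .fst import PairwiseMatrix, wc_fst
from .matrix_tests import mantel
from .quantgen import (
    bootstrap_components,
    fit_variance_components,
    heritability_fullsib,
    qst_point,
)
from .synthetic_data import (
    StudyDesign,
    TraitSpec,
    balding_nichols_genotypes,
    simulate_genotypes,
    simulate_phenotypes,
)


def _seed(master: int, k: int) -> int:
    return int((master * 1_000_003 + k) % (2**31 - 1))


def fst_recovery(seed: int = 0, n_rep: int = 20, n_pops: int = 8, n_per_pop: int = 30,
                 n_loci: int = 23, F: float = 0.10) -> dict:
    """Mean multi-locus theta over replicates of a Balding-Nichols panel."""
    thetas = [
        wc_fst(balding_nichols_genotypes(n_pops, n_per_pop, n_loci, F, _seed(seed, r))).theta
        for r in range(n_rep)
    ]
    return {"mean_theta": float(np.mean(thetas)), "n": n_rep, "target": F}


def _garden_design(n_pops, families, n_blocks, capacity, spec):
    return StudyDesign(
        n_pops={"ps": n_pops},
        families_per_pop=(families, families),
        sibs_per_family=2,
        n_blocks=n_blocks,
        block_capacity=capacity,
        n_loci=23,
        trait_specs={"t": spec},
    )


def qst_recovery(seed: int = 0, n_rep: int = 100, true_qst: float = 0.3) -> dict:
    """Mean Q_ST estimate at the full common-garden scale for a known truth.

    V_b is chosen so that V_b / (V_b + 4 V_w) equals ``true_qst``.
    """
    v_w = 0.25
    v_b = 4.0 * v_w * true_qst / (1.0 - true_qst)
    d = _garden_design(8, 25, 40, 24, TraitSpec(V_b=v_b, V_w=v_w, V_block=0.05, V_res=0.25))
    ests = []
    for r in range(n_rep):
        p, _, _ = simulate_phenotypes(d, _seed(seed, 100 + r))
        vc = fit_variance_components(p, "t")
        ests.append(qst_point(vc, heritability_fullsib(vc)).qst)
    return {"mean_qst": float(np.mean(ests)), "n": n_rep, "target": true_qst}


def reml_vs_anova(seed: int = 0, n_rep: int = 3) -> dict:
    """Largest deviation of REML from the balanced nested-ANOVA closed form."""
    worst = 0.0
    d = _garden_design(5, 8, 10, 8, TraitSpec(V_b=0.6, V_w=0.3, V_block=0.0, V_res=0.4))
    for r in range(n_rep):
        p, _, _ = simulate_phenotypes(d, _seed(seed, 200 + r))
        vc = fit_variance_components(p, "t", include_block=False)
        sub = p.trait_values("t")
        y = sub["t"].to_numpy()
        pops = sub["population"].to_numpy()
        fams = (sub["population"] + ":" + sub["family"]).to_numpy()
        pop_levels, fam_levels = np.unique(pops), np.unique(fams)
        s = y.size // fam_levels.size
        f = fam_levels.size // pop_levels.size
        grand = y.mean()
        pop_mean = {l: y[pops == l].mean() for l in pop_levels}
        fam_mean = {l: y[fams == l].mean() for l in fam_levels}
        ms_pop = s * f * sum((m - grand) ** 2 for m in pop_mean.values()) / (pop_levels.size - 1)
        ms_fam = s * sum(
            (fam_mean[l] - pop_mean[l.split(":")[0]]) ** 2 for l in fam_levels
        ) / (fam_levels.size - pop_levels.size)
        ms_res = sum((yi - fam_mean[l]) ** 2 for yi, l in zip(y, fams)) / (
            y.size - fam_levels.size
        )
        worst = max(
            worst,
            abs(vc.V_res - ms_res),
            abs(vc.V_w - (ms_fam - ms_res) / s),
            abs(vc.V_b - (ms_pop - ms_fam) / (s * f)),
        )
    return {"max_abs_diff": float(worst), "n": n_rep}


def neutral_null_type1(
    seed: int = 0,
    n_trials: int = 200,
    n_rep_null: int = 2000,
    cache_size: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the neutral-null comparison under pure neutrality.

    Every trial regenerates markers (Balding-Nichols at F = 0.10) and a
    trait whose among-population variance is itself drawn from the neutral
    model, runs the full comparison (theta with locus resampling, V_A
    bootstrap cache, chi-square deme sampling), and tests at ``alpha``.
    """
    d = _garden_design(
        8, 8, 16, 8, TraitSpec(V_b=0.0, V_w=0.25, V_block=0.05, V_res=0.25, neutral=True)
    )
    rejections = 0
    for t in range(n_trials):
        s = _seed(seed, 300 + t)
        g = simulate_genotypes(d, s)
        p, _, _ = simulate_phenotypes(d, s)
        est = wc_fst(g)
        vc = fit_variance_components(p, "t")
        h2 = heritability_fullsib(vc)
        q = qst_point(vc, h2)
        cache = 2.0 * np.asarray(
            [c.V_w for c in bootstrap_components(p, "t", cache_size, _seed(s, 1), vc=vc)]
        )
        null, _ = simulate_neutral_diff(est, cache, vc, n_rep_null, _seed(s, 2))
        res = bootstrap_null_pvalue(q.qst - est.theta, null, alpha=alpha)
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_trials, "n": n_trials, "alpha": alpha}


def mantel_sampled_vs_exact(seed: int = 0, n_perm: int = 10_000, size: int = 4) -> dict:
    """Gap between the sampled and exhaustively enumerated Mantel p at small n."""
    rng = np.random.default_rng(_seed(seed, 400))

    def rand_matrix():
        m = rng.random((size, size))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return PairwiseMatrix([f"p{i}" for i in range(size)], m)

    A, B = rand_matrix(), rand_matrix()
    exact = mantel(A, B)  # n <= 7 forces enumeration
    iu = np.triu_indices(size, 1)
    r_obs = np.corrcoef(A.values[iu], B.values[iu])[0, 1]
    hits = 0
    for _ in range(n_perm):
        pi = rng.permutation(size)
        r = np.corrcoef(A.values[iu], B.values[np.ix_(pi, pi)][iu])[0, 1]
        hits += r >= r_obs - 1e-12
    sampled = (1 + hits) / (n_perm + 1)
    return {
        "abs_gap": float(abs(sampled - exact.p)),
        "exact_p": float(exact.p),
        "sampled_p": float(sampled),
        "n": n_perm,
    }


def h2_ci_coverage(
    seed: int = 0, n_outer: int = 100, n_boot: int = 200, true_h2: float = 0.5
) -> dict:
    """Coverage of the 95% parametric-bootstrap CI for full-sib heritability.

    With h2 = 2 V_w / (V_w + V_res), the target 0.5 corresponds to
    V_res = 3 V_w.
    """
    v_w = 0.2
    v_res = v_w * (2.0 - true_h2) / true_h2
    d = _garden_design(6, 10, 15, 8, TraitSpec(V_b=0.2, V_w=v_w, V_block=0.05, V_res=v_res))
    covered = 0
    for r in range(n_outer):
        s = _seed(seed, 500 + r)
        p, _, _ = simulate_phenotypes(d, s)
        comps = bootstrap_components(p, "t", n_boot, _seed(s, 3))
        vals = [
            heritability_fullsib(c).h2 for c in comps if (c.V_w + c.V_res) > 0
        ]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        covered += lo <= true_h2 <= hi
    return {"coverage": covered / n_outer, "n": n_outer, "n_boot": n_boot}
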