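"""REML variance components against the balanced-ANOVA closed form and
lme4, plus heritability / Q_ST identities and the parametric bootstrap."""

import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qstfst import (
    PhenotypeTable,
    fit_variance_components,
    heritability_fullsib,
    parametric_bootstrap_ci,
    pairwise_qst,
    qst_point,
    sqrt_transform,
)
from qstfst import test_variance_component as lrt_variance_component
from qstfst.quantgen import VarianceComponents, apply_zeroing
from qstfst.synthetic_data import StudyDesign, TraitSpec, simulate_phenotypes
from helpers import small_design


def balanced_nested_anova(p: PhenotypeTable, trait: str):
    """Method-of-moments components for a balanced pop/family/sib design.

    Expected mean squares: MS_res = V_res, MS_fam = V_res + s V_w,
    MS_pop = V_res + s V_w + s f V_b with s sibs per family and f families
    per population.
    """
    sub = p.trait_values(trait)
    y = sub[trait].to_numpy()
    pops = sub["population"].to_numpy()
    fams = (sub["population"] + ":" + sub["family"]).to_numpy()
    pop_levels, fam_levels = np.unique(pops), np.unique(fams)
    s = len(y) // len(fam_levels)
    f = len(fam_levels) // len(pop_levels)
    grand = y.mean()
    pop_means = {l: y[pops == l].mean() for l in pop_levels}
    fam_means = {l: y[fams == l].mean() for l in fam_levels}
    ss_pop = s * f * sum((m - grand) ** 2 for m in pop_means.values())
    ss_fam = s * sum(
        (fam_means[l] - pop_means[l.split(":")[0]]) ** 2 for l in fam_levels
    )
    ss_res = sum((yi - fam_means[l]) ** 2 for yi, l in zip(y, fams))
    ms_pop = ss_pop / (len(pop_levels) - 1)
    ms_fam = ss_fam / (len(fam_levels) - len(pop_levels))
    ms_res = ss_res / (len(y) - len(fam_levels))
    v_res = ms_res
    v_w = (ms_fam - ms_res) / s
    v_b = (ms_pop - ms_fam) / (s * f)
    return v_b, v_w, v_res


def test_reml_equals_balanced_anova_oracle():
    d = small_design(
        n_pops=5, families=8, sibs=2,
        traits={"t": TraitSpec(V_b=0.6, V_w=0.3, V_block=0.0, V_res=0.4)},
        n_blocks=10, block_capacity=8,
    )
    p, _, _ = simulate_phenotypes(d, seed=2)
    vc = fit_variance_components(p, "t", include_block=False)
    v_b, v_w, v_res = balanced_nested_anova(p, "t")
    assert vc.V_b == pytest.approx(v_b, abs=1e-6)
    assert vc.V_w == pytest.approx(v_w, abs=1e-6)
    assert vc.V_res == pytest.approx(v_res, abs=1e-6)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_reml_matches_lme4_cross_check(tmp_path, small_study):
    _, p, _, _ = small_study
    vc = fit_variance_components(p, "t")
    csv = tmp_path / "d.csv"
    p.trait_values("t").to_csv(csv, index=False)
    script = (
        "suppressMessages(library(lme4));"
        f"d <- read.csv('{csv}');"
        "fit <- lmer(t ~ 1 + (1|population) + (1|population:family) + (1|block),"
        " data=d, REML=TRUE);"
        "v <- as.data.frame(VarCorr(fit));"
        "cat(v$vcov[v$grp=='population'], v$vcov[v$grp=='population:family'],"
        " v$vcov[v$grp=='block'], v$vcov[v$grp=='Residual'], as.numeric(logLik(fit)))"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    r_vb, r_vw, r_vblk, r_vres, r_ll = map(float, out.stdout.split())
    assert vc.V_b == pytest.approx(r_vb, abs=1e-4 + 1e-3 * r_vb)
    assert vc.V_w == pytest.approx(r_vw, abs=1e-4 + 1e-3 * r_vw)
    assert vc.V_block == pytest.approx(r_vblk, abs=1e-4 + 1e-3 * r_vblk)
    assert vc.V_res == pytest.approx(r_vres, abs=1e-4 + 1e-3 * r_vres)
    assert vc.log_likelihood == pytest.approx(r_ll, abs=1e-3)


def test_translation_and_scale_equivariance(small_study):
    _, p, _, _ = small_study
    vc = fit_variance_components(p, "t")
    shifted = PhenotypeTable(p.data.assign(t=p.data["t"] + 100.0), ["t"])
    vc_shift = fit_variance_components(shifted, "t")
    for attr in ("V_b", "V_w", "V_block", "V_res"):
        assert getattr(vc_shift, attr) == pytest.approx(getattr(vc, attr), rel=1e-6, abs=1e-9)
    c = 3.0
    scaled = PhenotypeTable(p.data.assign(t=p.data["t"] * c), ["t"])
    vc_scale = fit_variance_components(scaled, "t")
    for attr in ("V_b", "V_w", "V_block", "V_res"):
        assert getattr(vc_scale, attr) == pytest.approx(
            c**2 * getattr(vc, attr), rel=1e-5, abs=1e-8
        )
    h2, h2s = heritability_fullsib(vc), heritability_fullsib(vc_scale)
    assert h2s.h2 == pytest.approx(h2.h2, abs=1e-9)
    assert qst_point(vc_scale, h2s).qst == pytest.approx(qst_point(vc, h2).qst, abs=1e-9)


def test_zero_population_variance_hits_boundary():
    hits = 0
    n_rep = 12
    for seed in range(n_rep):
        d = small_design(
            traits={"t": TraitSpec(V_b=0.0, V_w=0.3, V_block=0.05, V_res=0.3)}
        )
        p, _, _ = simulate_phenotypes(d, seed=100 + seed)
        vc = fit_variance_components(p, "t")
        if vc.V_b <= 1e-8:
            hits += 1
    assert hits >= n_rep // 2


def test_lrt_boundary_mixture_formula(small_study):
    _, p, _, _ = small_study
    lrt, pval, zeroed = lrt_variance_component(p, "t", "family")
    # mixture p-value equals half the chi2(1) tail by construction
    assert pval == pytest.approx(0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0)
    assert lrt >= 0.0
    assert zeroed == (pval >= 0.05)


def test_lrt_power_for_strong_family_variance():
    # V_w = V_res at a realistic design size: the family component should be
    # detected in nearly every replicate
    detected = 0
    n_rep = 10
    for seed in range(n_rep):
        d = small_design(
            n_pops=8, families=20, n_blocks=40, block_capacity=8,
            traits={"t": TraitSpec(V_b=0.2, V_w=0.3, V_block=0.05, V_res=0.3)},
        )
        p, _, _ = simulate_phenotypes(d, seed=300 + seed)
        _, pval, _ = lrt_variance_component(p, "t", "family")
        detected += pval < 0.05
    assert detected >= round(0.9 * n_rep)


def test_lrt_zero_when_component_absent():
    d = small_design(traits={"t": TraitSpec(V_b=0.5, V_w=0.3, V_block=0.0, V_res=0.3)})
    p, _, _ = simulate_phenotypes(d, seed=42)
    lrt, pval, zeroed = lrt_variance_component(p, "t", "block")
    if lrt == 0.0:
        assert pval == 1.0
    assert zeroed


def test_heritability_closed_forms():
    vc = VarianceComponents(0, 0.0, 0, 1.0, 0, 0, 0, 0)
    assert heritability_fullsib(vc).h2 == 0.0
    vc = VarianceComponents(0, 1.0, 0, 1.0, 0, 0, 0, 0)
    assert heritability_fullsib(vc).h2 == 1.0
    vc = VarianceComponents(0, 1.0, 0, 3.0, 0, 0, 0, 0)
    assert heritability_fullsib(vc).h2 == 0.5
    vc = VarianceComponents(0, 3.0, 0, 1.0, 0, 0, 0, 0)
    with pytest.warns(UserWarning, match="exceeds 1"):
        assert heritability_fullsib(vc).h2 == 1.5
    with pytest.raises(ValueError):
        heritability_fullsib(VarianceComponents(0, 0.0, 0, 0.0, 0, 0, 0, 0))


def test_qst_point_identities():
    vc = VarianceComponents(0.0, 1.0, 0, 1.0, 0, 0, 0, 0)
    h2 = heritability_fullsib(vc)
    assert qst_point(vc, h2).qst == 0.0
    # V_b = 2 h2 (V_w + V_res) is the symmetry point
    vc = VarianceComponents(4.0, 1.0, 0, 1.0, 0, 0, 0, 0)
    h2 = heritability_fullsib(vc)
    assert qst_point(vc, h2).qst == pytest.approx(0.5)
    # Spitze formula reduces to V_b / (V_b + 4 V_w) with the full-sib h2
    vc = VarianceComponents(4.0, 1.0, 0, 2.5, 0, 0, 0, 0)
    h2 = heritability_fullsib(vc)
    reduced = vc.V_b / (vc.V_b + 4.0 * vc.V_w)
    assert qst_point(vc, h2).qst == pytest.approx(reduced, abs=1e-12)
    with pytest.raises(ValueError):
        qst_point(VarianceComponents(0.0, 0.0, 0, 1.0, 0, 0, 0, 0),
                  type(h2)(h2=0.0))


def test_sqrt_transform_shifts_negatives():
    x = np.array([-1.0, 0.0, 3.0])
    out = sqrt_transform(x)
    assert out[0] == 0.0
    assert out == pytest.approx(np.sqrt(x + 1.0))
    y = np.array([1.0, 4.0])
    assert sqrt_transform(y) == pytest.approx([1.0, 2.0])


def test_pairwise_qst_structure_and_duplicate_population(small_study):
    _, p, _, _ = small_study
    vc = fit_variance_components(p, "t")
    h2 = heritability_fullsib(vc)
    mat = pairwise_qst(p, "t", h2, zeroing=False)
    assert mat.labels == p.populations
    assert np.allclose(np.diag(mat.values), 0.0)
    assert np.allclose(mat.values, mat.values.T, equal_nan=True)
    # a population duplicated under a new label has V_b = 0 against itself
    dup = p.data[p.data["population"] == "ps1"].copy()
    dup["population"] = "dup"
    dup["individual"] = dup["individual"] + "x"
    both = PhenotypeTable(pd.concat([p.data, dup], ignore_index=True), ["t"])
    mat2 = pairwise_qst(both, "t", h2, zeroing=False)
    assert mat2.get("ps1", "dup") == pytest.approx(0.0, abs=1e-6)


def test_pairwise_qst_null_simulation():
    # populations simulated with identical means: median pairwise Q_ST small
    meds = []
    for seed in range(5):
        d = small_design(
            n_pops=3, families=8,
            traits={"t": TraitSpec(V_b=0.0, V_w=0.3, V_block=0.02, V_res=0.3)},
        )
        p, _, _ = simulate_phenotypes(d, seed=200 + seed)
        vc = fit_variance_components(p, "t")
        h2 = heritability_fullsib(vc)
        mat = pairwise_qst(p, "t", h2, zeroing=False)
        meds.append(np.nanmedian(mat.offdiag()))
    assert np.median(meds) < 0.05


def test_bootstrap_ci_determinism_and_coverage_direction(small_study):
    _, p, _, _ = small_study
    lo1, hi1 = parametric_bootstrap_ci(p, "t", "h2", n_boot=200, seed=7)
    lo2, hi2 = parametric_bootstrap_ci(p, "t", "h2", n_boot=200, seed=7)
    assert (lo1, hi1) == (lo2, hi2)
    assert lo1 < hi1
    assert lo1 >= 0.0
    with pytest.raises(ValueError):
        parametric_bootstrap_ci(p, "t", "h2", n_boot=50, seed=1)


def test_apply_zeroing_zeroes_weak_components():
    d = small_design(traits={"t": TraitSpec(V_b=0.0, V_w=0.4, V_block=0.0, V_res=0.4)})
    p, _, _ = simulate_phenotypes(d, seed=77)
    vc = fit_variance_components(p, "t")
    vc0 = apply_zeroing(p, "t", vc)
    assert vc0.V_b == 0.0 or vc0.V_b == vc.V_b  # zeroed unless clearly supported
    assert vc0.V_res == vc.V_res
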