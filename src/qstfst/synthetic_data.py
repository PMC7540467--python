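"""Synthetic common-garden studies with known truth.

The generator emulates the snapdragon study design this pipeline targets:
thirteen populations in two subspecies sampled along an altitudinal
gradient, 9-42 full-sib families per population with two sibs each, a
randomized block layout of 40 containers holding 24 plants, and 23
multi-allelic neutral markers differentiated at F_ST ~ 0.10.

Genotypes follow the Balding-Nichols F-model: per locus an ancestral allele
frequency vector is drawn from a flat Dirichlet and each population's
frequencies from Dirichlet(p_anc * (1-F)/F), so the expected differentiation
equals the target F.  Phenotypes follow the additive random-effects model
the analysis assumes: population, family, block and residual effects are
independent zero-mean Gaussians with the variances given per trait, plus an
optional linear altitude cline on the population means.  A trait may
instead be declared ``neutral``: its among-population variance is then drawn
from the neutral expectation 2F/(1-F) * V_A * chi2_d/d (V_A = 2 V_w,
d = n_pops - 1), which makes end-to-end type-I calibration of the
neutrality test possible.

Genotypes and phenotypes are statistically independent (no marker-trait
linkage), matching the neutral-marker assumption of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GenotypeTable,
    PhenotypeTable,
    PopulationMetadata,
    write_genepop,
    write_phenotype_csv,
    write_population_metadata,
)


@dataclass
class TraitSpec:
    """Generating parameters for one trait (variances in trait units^2)."""

    V_b: float = 0.25
    V_w: float = 0.25
    V_block: float = 0.05
    V_res: float = 0.25
    altitude_slope: float = 0.0  # trait units per metre
    mean: float = 10.0
    neutral: bool = False  # draw V_b from the neutral model instead

    def __post_init__(self) -> None:
        if min(self.V_b, self.V_w, self.V_block, self.V_res) < 0:
            raise ValueError("variances must be non-negative")


def _default_traits() -> dict:
    return {"trait1": TraitSpec()}


@dataclass
class StudyDesign:
    """Sampling and crossing design of a simulated common-garden study."""

    n_pops: dict = field(default_factory=lambda: {"pseudomajus": 8, "striatum": 5})
    families_per_pop: tuple = (9, 42)
    sibs_per_family: int = 2
    n_blocks: int = 40
    block_capacity: int = 24
    n_loci: int = 23
    alleles_per_locus: tuple = (3, 12)
    target_fst: float = 0.10
    trait_specs: dict = field(default_factory=_default_traits)
    altitude_range: tuple = (61.0, 1564.0)
    missing_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fst < 1.0:
            raise ValueError("target_fst must be in (0, 1)")
        if self.families_per_pop[0] > self.families_per_pop[1]:
            raise ValueError("families_per_pop range reversed")
        max_plants = self.total_populations() * self.families_per_pop[1] * self.sibs_per_family
        if max_plants > self.n_blocks * self.block_capacity:
            raise ValueError(
                f"up to {max_plants} plants cannot fit {self.n_blocks} blocks "
                f"of {self.block_capacity}"
            )

    def total_populations(self) -> int:
        return sum(self.n_pops.values())


_PREFIX = {"pseudomajus": "ps", "striatum": "st"}


@dataclass
class DesignRealization:
    """Concrete layout drawn from a StudyDesign: who grows where."""

    populations: list  # population label per subspecies order
    subspecies_of: dict
    families: dict  # population -> family labels
    individuals: list  # (id, population, family)
    blocks: dict  # individual id -> block label
    altitudes: dict  # population -> altitude (m)


def realize_design(d: StudyDesign, seed: int) -> DesignRealization:
    """Draw family counts, altitudes and the randomized block fill."""
    rng = np.random.default_rng([int(seed), 1])
    populations, subspecies_of = [], {}
    for subsp, k in d.n_pops.items():
        prefix = _PREFIX.get(subsp, subsp[:2])
        for i in range(k):
            label = f"{prefix}{i + 1}"
            populations.append(label)
            subspecies_of[label] = subsp

    lo, hi = d.families_per_pop
    families, individuals = {}, []
    for pop in populations:
        nfam = int(rng.integers(lo, hi + 1))
        fams = [f"F{j + 1:02d}" for j in range(nfam)]
        families[pop] = fams
        for fam in fams:
            for s in range(d.sibs_per_family):
                individuals.append((f"{pop}_{fam}_S{s + 1}", pop, fam))

    if len(individuals) > d.n_blocks * d.block_capacity:
        raise ValueError("realized design exceeds block capacity")
    order = rng.permutation(len(individuals))
    blocks = {}
    for slot, idx in enumerate(order):
        blocks[individuals[idx][0]] = f"B{slot // d.block_capacity + 1:02d}"

    alts = rng.uniform(d.altitude_range[0], d.altitude_range[1], size=len(populations))
    altitudes = {pop: float(a) for pop, a in zip(populations, alts)}
    return DesignRealization(populations, subspecies_of, families, individuals, blocks, altitudes)


def simulate_genotypes(d: StudyDesign, seed: int) -> GenotypeTable:
    """Balding-Nichols genotypes at the design's target F for every plant."""
    real = realize_design(d, seed)
    rng = np.random.default_rng([int(seed), 2])
    F = d.target_fst
    pops = real.populations
    pop_index = {p: i for i, p in enumerate(pops)}
    n = len(real.individuals)
    loci = [f"L{j + 1:02d}" for j in range(d.n_loci)]
    calls = np.zeros((n, d.n_loci, 2), dtype=np.int64)
    ind_pop = np.array([pop_index[p] for _, p, _ in real.individuals])
    for j in range(d.n_loci):
        k = int(rng.integers(d.alleles_per_locus[0], d.alleles_per_locus[1] + 1))
        p_anc = rng.dirichlet(np.ones(k))
        pop_freqs = np.vstack(
            [rng.dirichlet(p_anc * (1.0 - F) / F) for _ in pops]
        )
        for pi in range(len(pops)):
            rows = np.where(ind_pop == pi)[0]
            calls[rows, j] = rng.choice(k, size=(rows.size, 2), p=pop_freqs[pi]) + 1
    if d.missing_rate > 0:
        miss = rng.random((n, d.n_loci)) < d.missing_rate
        calls[miss] = 0
    populations = np.array([p for _, p, _ in real.individuals], dtype=object)
    return GenotypeTable([i for i, _, _ in real.individuals], populations, loci, calls)


def balding_nichols_genotypes(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    F: float,
    seed: int,
    alleles_per_locus: tuple = (3, 12),
) -> GenotypeTable:
    """Plain Balding-Nichols panel (no family structure), for estimator checks."""
    if not 0.0 < F < 1.0:
        raise ValueError("F must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    n = n_pops * n_per_pop
    calls = np.zeros((n, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        k = int(rng.integers(alleles_per_locus[0], alleles_per_locus[1] + 1))
        p_anc = rng.dirichlet(np.ones(k))
        for pi in range(n_pops):
            freqs = rng.dirichlet(p_anc * (1.0 - F) / F)
            rows = slice(pi * n_per_pop, (pi + 1) * n_per_pop)
            calls[rows, j] = rng.choice(k, size=(n_per_pop, 2), p=freqs) + 1
    individuals = [f"{p}_{i + 1}" for p in pops for i in range(n_per_pop)]
    populations = np.repeat(pops, n_per_pop).astype(object)
    return GenotypeTable(individuals, populations, loci, calls)


def _neutral_vb(rng, F: float, V_w: float, n_pops: int) -> float:
    va = 2.0 * V_w
    d = n_pops - 1
    return 2.0 * F / (1.0 - F) * va * rng.chisquare(d) / d


def simulate_phenotypes(d: StudyDesign, seed: int):
    """Simulate the phenotype table, metadata, and the generating truth.

    Returns ``(PhenotypeTable, PopulationMetadata, truth)`` where ``truth``
    records the per-trait generating variances (after any neutral-model
    draw of V_b) and the realized design counts, for recovery testing.
    """
    real = realize_design(d, seed)
    rng = np.random.default_rng([int(seed), 3])
    pops = real.populations
    rows = {
        "individual": [i for i, _, _ in real.individuals],
        "subspecies": [real.subspecies_of[p] for _, p, _ in real.individuals],
        "population": [p for _, p, _ in real.individuals],
        "family": [f for _, _, f in real.individuals],
        "block": [real.blocks[i] for i, _, _ in real.individuals],
    }
    pop_of = np.array(rows["population"])
    fam_of = np.array([f"{p}:{f}" for _, p, f in real.individuals])
    blk_of = np.array(rows["block"])
    fam_levels = list(dict.fromkeys(fam_of))
    blk_levels = list(dict.fromkeys(blk_of))

    truth = {
        "target_fst": d.target_fst,
        "n_pops": dict(d.n_pops),
        "families_per_pop": {p: len(real.families[p]) for p in pops},
        "altitudes": dict(real.altitudes),
        "traits": {},
    }
    data = pd.DataFrame(rows)
    for name, spec in d.trait_specs.items():
        v_b = spec.V_b
        if spec.neutral:
            v_b = _neutral_vb(rng, d.target_fst, spec.V_w, len(pops))
        pop_eff = {p: rng.normal(0.0, np.sqrt(v_b)) for p in pops}
        fam_eff = {f: rng.normal(0.0, np.sqrt(spec.V_w)) for f in fam_levels}
        blk_eff = {b: rng.normal(0.0, np.sqrt(spec.V_block)) for b in blk_levels}
        resid = rng.normal(0.0, np.sqrt(spec.V_res), len(data))
        alt = np.array([real.altitudes[p] for p in pop_of])
        y = (
            spec.mean
            + spec.altitude_slope * alt
            + np.array([pop_eff[p] for p in pop_of])
            + np.array([fam_eff[f] for f in fam_of])
            + np.array([blk_eff[b] for b in blk_of])
            + resid
        )
        data[name] = y
        pop_means = {
            p: float(spec.mean + spec.altitude_slope * real.altitudes[p] + pop_eff[p])
            for p in pops
        }
        truth["traits"][name] = {
            "population_means": pop_means,
            "V_b": float(v_b),
            "V_w": spec.V_w,
            "V_block": spec.V_block,
            "V_res": spec.V_res,
            "altitude_slope": spec.altitude_slope,
            "mean": spec.mean,
            "neutral": spec.neutral,
            "true_qst": float(v_b / (v_b + 4.0 * spec.V_w)) if (v_b + spec.V_w) > 0 else 0.0,
        }

    # coordinates: a plausible window over the eastern Pyrenees
    meta_rng = np.random.default_rng([int(seed), 4])
    meta = pd.DataFrame(
        {
            "population": pops,
            "subspecies": [real.subspecies_of[p] for p in pops],
            "latitude": np.round(meta_rng.uniform(42.0, 43.2, len(pops)), 5),
            "longitude": np.round(meta_rng.uniform(0.5, 3.0, len(pops)), 5),
            "altitude": [real.altitudes[p] for p in pops],
        }
    )
    return PhenotypeTable(data), PopulationMetadata(meta), truth


def fixture_design(seed: int = 0) -> StudyDesign:
    """Miniature four-trait study used by the end-to-end fixtures.

    One neutral trait (V_b from the neutral model), one divergent trait
    (true Q_ST = 0.8), one uniform trait (Q_ST ~ 0.01) and one altitudinal
    cline, on an 8-population single-subspecies design small enough for the
    whole pipeline to run in minutes.
    """
    return StudyDesign(
        n_pops={"pseudomajus": 8},
        families_per_pop=(10, 10),
        sibs_per_family=2,
        n_blocks=10,
        block_capacity=16,
        n_loci=23,
        alleles_per_locus=(3, 12),
        target_fst=0.10,
        trait_specs={
            "neutral": TraitSpec(V_w=0.25, V_block=0.05, V_res=0.25, neutral=True),
            "divergent": TraitSpec(V_b=4.0, V_w=0.25, V_block=0.05, V_res=0.25),
            "uniform": TraitSpec(V_b=0.01, V_w=0.25, V_block=0.05, V_res=0.25),
            "cline": TraitSpec(V_b=0.1, V_w=0.25, V_block=0.05, V_res=0.25,
                               altitude_slope=0.00125),
        },
        master_seed=seed,
    )


def generate_fixture_study(seed: int, out_dir) -> dict:
    """Write a complete miniature study bundle and return its file paths.

    Files: ``genotypes.gen`` (GenePop), ``phenotypes.csv``, ``metadata.csv``
    and ``truth.yaml`` holding the generating parameters.  Regeneration with
    the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = fixture_design(seed)
    g = simulate_genotypes(d, seed)
    p, m, truth = simulate_phenotypes(d, seed)
    paths = {
        "genotypes": out / "genotypes.gen",
        "phenotypes": out / "phenotypes.csv",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.yaml",
    }
    write_genepop(g, paths["genotypes"], title="synthetic common-garden fixture")
    write_phenotype_csv(p, paths["phenotypes"])
    write_population_metadata(m, paths["metadata"])
    truth = dict(truth, seed=int(seed))
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
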