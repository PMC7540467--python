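"""Shared builders for compact simulated studies used across the suite."""

from qstfst.synthetic_data import StudyDesign, TraitSpec


def small_design(
    n_pops=4,
    families=6,
    sibs=2,
    n_blocks=8,
    block_capacity=8,
    traits=None,
    seed=0,
):
    """Compact balanced study design (single subspecies) for fast REML fits."""
    traits = traits or {"t": TraitSpec(V_b=0.5, V_w=0.25, V_block=0.05, V_res=0.25)}
    required = n_pops * families * sibs
    n_blocks = max(n_blocks, -(-required // block_capacity))
    return StudyDesign(
        n_pops={"ps": n_pops},
        families_per_pop=(families, families),
        sibs_per_family=sibs,
        n_blocks=n_blocks,
        block_capacity=block_capacity,
        n_loci=6,
        trait_specs=traits,
        master_seed=seed,
    )
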