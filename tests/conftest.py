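"""Shared fixtures: small ground-truthed simulations reused across tests."""

from __future__ import annotations

import pytest

from ohnolog import pipeline as PL
from ohnolog.simulate import SimConfig, base_pair_id, copy_label, simulate


def truth_info(gene_id: str) -> tuple[str | None, str | None]:
    """(ancestral pair id, copy label) encoded in a dataset gene id."""
    local = gene_id.split("_", 1)[1] if "_" in gene_id else gene_id
    return base_pair_id(local), copy_label(local)


@pytest.fixture(scope="session")
def small_full_sim():
    """5 ingroup species + 1 outgroup with sequences, 120 genes."""
    cfg = SimConfig(n_genes=120, n_scaffolds=4, n_ingroup=5, n_outgroup=1, seed=21)
    genomes, tree, truth = simulate(cfg)
    return cfg, genomes, tree, truth


@pytest.fixture(scope="session")
def small_pipeline(small_full_sim):
    """Within-species paralogons and gene families for the small sim."""
    _, genomes, _, _ = small_full_sim
    ingroup = {s: g for s, g in genomes.items() if s.startswith("sp")}
    per_species = PL.within_species_paralogons(ingroup)
    families = PL.build_families(ingroup, {s: per_species[s][0] for s in per_species})
    return ingroup, per_species, families


@pytest.fixture(scope="session")
def loss_only_sim():
    """13-species loss-only simulation, 3000 pairs, default dynamics."""
    cfg = SimConfig(
        n_genes=3000, n_ingroup=13, n_outgroup=2, evolve_sequences=False, seed=7
    )
    genomes, tree, truth = simulate(cfg)
    return cfg, tree, truth
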