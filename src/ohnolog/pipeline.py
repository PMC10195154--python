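"""End-to-end glue: run the whole analysis on a set of per-species genomes.

These helpers wire the stage modules together the way the examples and the
reproduction script use them: within-species RBH and paralogons, a global
RBH graph and gene families, family gene trees, and a family-based
presence matrix feeding the loss-dynamics stage.
"""

from __future__ import annotations

import logging

import pandas as pd

from .homology import (
    build_gene_tree,
    cluster_families,
    reciprocal_best_hits,
    within_genome_rbh,
)
from .models import GeneModel, BOTH, ONE, NA
from .orthology import cds_distance
from .paralogon import detect_paralogons
from .simulate import copy_label

logger = logging.getLogger(__name__)


def species_of(gene_id: str) -> str:
    """Species prefix of a dataset gene id (``<species>_<gene>``)."""
    return gene_id.split("_", 1)[0]


def within_species_paralogons(
    genomes: dict[str, list[GeneModel]], **kwargs
) -> dict[str, tuple[list[tuple[str, str]], list]]:
    """Per species: (within-genome RBH pairs, called paralogons)."""
    out = {}
    for sp in sorted(genomes):
        rbh = within_genome_rbh(genomes[sp])
        pars = detect_paralogons(genomes[sp], rbh, **kwargs)
        out[sp] = (rbh, pars)
        logger.info("%s: %d RBH pairs, %d paralogons", sp, len(rbh), len(pars))
    return out


def cross_species_edges(
    genomes: dict[str, list[GeneModel]], species: list[str] | None = None
) -> list[tuple[str, str]]:
    """RBH edges for every species pair (used to cluster gene families)."""
    species = sorted(species or genomes)
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            edges.extend(reciprocal_best_hits(genomes[a], genomes[b]))
    return edges


def build_families(
    genomes: dict[str, list[GeneModel]],
    within_rbh: dict[str, list[tuple[str, str]]] | None = None,
) -> dict[str, list[str]]:
    """Gene families: connected components of the cross-species RBH graph
    augmented with each species' within-genome (ohnolog) RBH pairs."""
    edges = cross_species_edges(genomes)
    if within_rbh is None:
        within_rbh = {sp: within_genome_rbh(genomes[sp]) for sp in sorted(genomes)}
    within_edges = [e for sp in sorted(within_rbh) for e in within_rbh[sp]]
    return cluster_families(edges, within_edges)


def family_gene_trees(
    families: dict[str, list[str]], genomes: dict[str, list[GeneModel]]
) -> dict[str, str]:
    """NJ gene tree (newick) per family of size >= 3.

    Distances are CDS p-distances: under the strong purifying selection
    typical of retained ohnologs, the copy split is visible mainly at
    silent sites (protein distances fall back in for unequal lengths).
    """
    import numpy as np

    gene = {g.gene_id: g for genes in genomes.values() for g in genes}
    trees = {}
    for fam in sorted(families):
        members = sorted(m for m in families[fam] if m in gene)
        if len(members) < 3:
            continue
        n = len(members)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = cds_distance(gene[members[i]], gene[members[j]])
                dist[i, j] = dist[j, i] = d
        trees[fam] = build_gene_tree(
            {m: gene[m].protein for m in members}, distances=dist
        )
    return trees


def presence_from_families(
    families: dict[str, list[str]],
    ingroup: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Family-based presence matrix over ingroup species.

    Cell = BOTH when a species keeps two family members (the ohnolog
    pair), ONE with a single member, NA when the species is absent from
    the family. Families with more than two members in any species (e.g.
    tandem duplicates) are skipped. Also returns a copy-identity matrix
    ('A'/'B' by simulated copy label where unambiguous, '' otherwise) for
    parallel/reciprocal classification.
    """
    rows_state, rows_copy, index = [], [], []
    for fam in sorted(families):
        per_sp: dict[str, list[str]] = {}
        for m in families[fam]:
            per_sp.setdefault(species_of(m), []).append(m)
        counts = {sp: len(per_sp.get(sp, [])) for sp in ingroup}
        if any(c > 2 for c in counts.values()):
            continue
        if all(c == 0 for c in counts.values()):
            continue
        state, copy_row = {}, {}
        for sp in ingroup:
            c = counts[sp]
            if c == 0:
                state[sp], copy_row[sp] = NA, ""
            elif c == 2:
                state[sp], copy_row[sp] = BOTH, ""
            else:
                state[sp] = ONE
                copy_row[sp] = copy_label(per_sp[sp][0]) or ""
        rows_state.append(state)
        rows_copy.append(copy_row)
        index.append(fam)
    states = pd.DataFrame(rows_state, index=index, columns=ingroup)
    copies = pd.DataFrame(rows_copy, index=index, columns=ingroup)
    return states, copies
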