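"""MAPS-style placement of WGD events from ladderized 4-taxon gene subtrees.

For a fixed ladder quartet (((T1, T2), T3), OUT), every gene tree is pruned
to copies of the four taxa (skipped unless all four are represented), the
subtree is rooted on the OUT copies, and the deepest species-overlap
duplication node votes for the ladder branch above the MRCA of the species
it spans. Support percentages over all subtrees are banded as in a
standard MAPS report (>=50%, >=25%, <25%).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import pandas as pd

BANDS = ((50.0, "orange"), (25.0, "blue"), (0.0, "grey"))


@dataclass(frozen=True)
class LadderQuartet:
    """Taxa of one ladder: (((t1, t2), t3), outgroup)."""

    t1: str
    t2: str
    t3: str
    outgroup: str

    @property
    def taxa(self) -> tuple[str, str, str, str]:
        return (self.t1, self.t2, self.t3, self.outgroup)

    def branch_of(self, species: frozenset[str]) -> str:
        """Ladder branch above the MRCA of a species set."""
        if self.outgroup in species:
            return "root"
        if self.t3 in species:
            return "t1t2t3" if len(species) > 1 else "t3"
        if len(species) == 2:
            return "t1t2"
        if species == {self.t1}:
            return "t1"
        if species == {self.t2}:
            return "t2"
        return "t1t2t3"


def extract_subtree(
    gene_tree: dendropy.Tree | str, quartet: LadderQuartet, species_of
) -> dendropy.Tree | None:
    """Prune a gene tree to the quartet taxa; None unless every taxon has
    at least one gene copy."""
    if isinstance(gene_tree, str):
        gene_tree = dendropy.Tree.get(data=gene_tree, schema="newick", preserve_underscores=True)
    tree = gene_tree.clone(depth=1)
    keep = [
        lf.taxon for lf in tree.leaf_node_iter() if species_of(lf.taxon.label) in quartet.taxa
    ]
    present = {species_of(t.label) for t in keep}
    if present != set(quartet.taxa):
        return None
    tree.retain_taxa(keep)
    tree.is_rooted = True
    return tree


def _root_at_outgroup(tree: dendropy.Tree, quartet: LadderQuartet, species_of) -> dendropy.Tree:
    out_leaves = sorted(
        (lf for lf in tree.leaf_node_iter() if species_of(lf.taxon.label) == quartet.outgroup),
        key=lambda lf: lf.taxon.label,
    )
    node = out_leaves[0]
    if node.edge.length is None:
        node.edge.length = 0.0
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def duplication_branch(
    subtree: dendropy.Tree, quartet: LadderQuartet, species_of
) -> str | None:
    """Ladder branch voted by the deepest species-overlap duplication node
    of one subtree; None when the subtree shows no duplication."""
    tree = _root_at_outgroup(subtree.clone(depth=1), quartet, species_of)
    species_sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            species_sets[id(node)] = frozenset({species_of(node.taxon.label)})
        else:
            kids = node.child_nodes()
            species_sets[id(node)] = frozenset().union(*(species_sets[id(k)] for k in kids))
    for node in tree.preorder_node_iter():  # deepest (closest to root) first
        kids = node.child_nodes()
        if len(kids) < 2:
            continue
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                if species_sets[id(kids[i])] & species_sets[id(kids[j])]:
                    return quartet.branch_of(species_sets[id(node)])
    return None


def vote_placement(
    subtrees: list[dendropy.Tree], quartet: LadderQuartet, species_of
) -> pd.DataFrame:
    """Percentage of subtrees placing a duplication on each ladder branch.

    Subtrees without any duplication node vote 'unassigned'; percentages
    (including unassigned) sum to 100.
    """
    if not subtrees:
        raise ValueError("need >= 1 subtree")
    votes: Counter[str] = Counter()
    for st in subtrees:
        branch = duplication_branch(st, quartet, species_of)
        votes[branch or "unassigned"] += 1
    total = sum(votes.values())
    branches = ["root", "t1t2t3", "t1t2", "t1", "t2", "t3", "unassigned"]
    rows = []
    for b in branches:
        pct = 100.0 * votes.get(b, 0) / total
        band = next(name for cut, name in BANDS if pct >= cut)
        rows.append((b, pct, band, votes.get(b, 0)))
    return pd.DataFrame(rows, columns=["branch", "percent", "band", "n"])
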