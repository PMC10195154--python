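"""Cross-species orthology: synteny-weighted assignment, 1-to-2 resolution,
gene-tree ortholog groups, and paralogon chaining across species.

Because the species radiated right after the WGD, a gene's best cross-
species hit can be the wrong ohnolog copy; scaffold-level "orthology
scores" (the number of ortholog pairs linking two scaffolds) supply the
synteny signal that disambiguates the copies, and gene trees rooted at the
copy split group genes into per-copy ortholog groups that chain paralogons
across species.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import dendropy
import networkx as nx

from .models import GeneModel
from .homology import _ALIGNER

logger = logging.getLogger(__name__)


@dataclass
class OrthologCall:
    gene_a: str
    gene_b: str
    kind: str  # '1to1' | '1to2' | '2to2' | 'resolved' | 'unresolved'
    alternatives: tuple[str, ...] = ()
    confident: bool = False


def _score(ga: GeneModel, gb: GeneModel) -> float:
    return float(_ALIGNER.score(ga.protein, gb.protein))


def cds_distance(ga: GeneModel, gb: GeneModel) -> float:
    """Nucleotide p-distance between two genes' CDS.

    Ohnolog copies evolve under strong purifying selection, so the two
    copies are barely distinguishable at the protein level; most of the
    copy-discriminating divergence sits at silent sites, which makes the
    nucleotide distance the right within-family similarity measure.
    Falls back to protein p-distance for unalignable lengths.
    """
    a, b = ga.cds, gb.cds
    if len(a) == len(b) and a:
        return sum(1 for x, y in zip(a, b) if x != y) / len(a)
    from .homology import protein_p_distance

    return protein_p_distance(ga.protein, gb.protein)


def initial_orthologs(
    genes_a: dict[str, GeneModel],
    genes_b: dict[str, GeneModel],
    families: dict[str, list[str]],
    wgd_pairs_a: set[tuple[str, str]] | None = None,
    wgd_pairs_b: set[tuple[str, str]] | None = None,
    confident_margin: float = 0.0,
) -> list[OrthologCall]:
    """Within-family mutual closest pairs between two species, annotated
    with orthology multiplicity (1-to-1 / 1-to-2 / 2-to-2).

    Similarity is CDS p-distance (see :func:`cds_distance`). Calls that
    actually chose between the two WGD copies (1-to-2 and 2-to-2) are
    marked confident when the runner-up candidate is at least
    ``confident_margin`` more distant; these copy-informative calls feed
    the scaffold scores. 1-to-1 calls are forced pairings — at a locus
    where each species keeps a single gene the genes pair regardless of
    which copy survived, so they carry no copy signal and are never
    confident. ``wgd_pairs_*`` are each species' detected ohnolog pairs;
    a 1-to-2 call records the two candidate copies as ``alternatives``
    for scaffold-score resolution.
    """
    partner_a = _partner_map(wgd_pairs_a)
    partner_b = _partner_map(wgd_pairs_b)
    calls: list[OrthologCall] = []
    for fam in sorted(families):
        ma = sorted(m for m in families[fam] if m in genes_a)
        mb = sorted(m for m in families[fam] if m in genes_b)
        if not ma or not mb:
            continue
        dist = {(a, b): cds_distance(genes_a[a], genes_b[b]) for a in ma for b in mb}
        best_a = {a: min(mb, key=lambda b: (dist[(a, b)], b)) for a in ma}
        best_b = {b: min(ma, key=lambda a: (dist[(a, b)], a)) for b in mb}
        for a in ma:
            b = best_a[a]
            if best_b[b] != a:
                continue
            margin = 1.0
            if len(mb) > 1:
                second = min(dist[(a, x)] for x in mb if x != b)
                margin = second - dist[(a, b)]
            if len(ma) > 1:
                second_a = min(dist[(x, b)] for x in ma if x != a)
                margin = min(margin, second_a - dist[(a, b)])
            a2, b2 = partner_a.get(a), partner_b.get(b)
            two_a = a2 in genes_a and a2 in families[fam] if a2 else False
            two_b = b2 in genes_b and b2 in families[fam] if b2 else False
            confident = margin >= confident_margin
            if two_b and not two_a:
                calls.append(OrthologCall(a, b, "1to2", (b, b2), confident))
            elif two_a and not two_b:
                calls.append(OrthologCall(a, b, "1to2", (a, a2), confident))
            elif two_a and two_b:
                calls.append(OrthologCall(a, b, "2to2", (), confident))
            else:
                calls.append(OrthologCall(a, b, "1to1", (), False))
    return calls


def _partner_map(pairs: set[tuple[str, str]] | None) -> dict[str, str]:
    out: dict[str, str] = {}
    for a, b in pairs or ():
        out[a] = b
        out[b] = a
    return out


def score_scaffolds(
    calls: list[OrthologCall],
    pos_a: dict[str, tuple[str, int]],
    pos_b: dict[str, tuple[str, int]],
    confident_only: bool = False,
) -> dict[tuple[str, str], int]:
    """Orthology score per scaffold pair: the number of candidate ortholog
    pairs linking the two scaffolds (optionally confident calls only —
    the aggregation that lets block-level evidence resolve copies
    individual genes cannot)."""
    scores: dict[tuple[str, str], int] = defaultdict(int)
    for c in calls:
        if confident_only and not c.confident:
            continue
        sa = pos_a[c.gene_a][0]
        sb = pos_b[c.gene_b][0]
        scores[(sa, sb)] += 1
    return dict(scores)


def scaffold_link_distances(
    genes_a: dict[str, GeneModel],
    genes_b: dict[str, GeneModel],
    families: dict[str, list[str]],
) -> dict[tuple[str, str], float]:
    """Mean within-family CDS p-distance of the gene links between each
    scaffold pair.

    Scaffold pairs descending from the same WGD copy are systematically
    closer than mirror (cross-copy) pairs, and averaging over all loci on
    a scaffold makes the tiny per-gene signal decisive even for species
    that split right after the WGD. Used as the divergence channel of the
    scaffold orthology score.
    """
    acc: dict[tuple[str, str], list[float]] = defaultdict(list)
    for fam in sorted(families):
        ma = sorted(m for m in families[fam] if m in genes_a)
        mb = sorted(m for m in families[fam] if m in genes_b)
        for a in ma:
            for b in mb:
                acc[(genes_a[a].scaffold, genes_b[b].scaffold)].append(
                    cds_distance(genes_a[a], genes_b[b])
                )
    return {k: sum(v) / len(v) for k, v in acc.items()}


def resolve_one_to_two(
    call: OrthologCall,
    scores: dict[tuple[str, str], int],
    pos_a: dict[str, tuple[str, int]],
    pos_b: dict[str, tuple[str, int]],
    link_distances: dict[tuple[str, str], float] | None = None,
) -> OrthologCall:
    """Convert a 1-to-2 call to 1-to-1 by picking the copy whose scaffold
    pair carries the higher orthology score; ties stay unresolved.

    With ``link_distances`` the scaffold comparison uses the aggregate
    divergence channel (lower mean link distance wins) and falls back to
    the call-count score on ties/missing data — count votes alone are
    uninformative when ohnolog copies are nearly identical at the protein
    level.
    """
    if call.kind != "1to2":
        return call
    g1, g2 = call.alternatives
    if g1 in pos_b or g2 in pos_b:  # the "2" side is in species B
        single, cands, pos_s, pos_c = call.gene_a, (g1, g2), pos_a, pos_b
        def skey(c):
            return (pos_s[single][0], pos_c[c][0])
    else:  # the "2" side is in species A
        single, cands, pos_s, pos_c = call.gene_b, (g1, g2), pos_b, pos_a
        def skey(c):
            return (pos_c[c][0], pos_s[single][0])
    chosen = None
    if link_distances is not None:
        d1 = link_distances.get(skey(cands[0]))
        d2 = link_distances.get(skey(cands[1]))
        if d1 is not None and d2 is not None and d1 != d2:
            chosen = cands[0] if d1 < d2 else cands[1]
    if chosen is None:
        s1, s2 = scores.get(skey(cands[0]), 0), scores.get(skey(cands[1]), 0)
        if s1 == s2:
            logger.debug("unresolved 1-to-2 for %s", single)
            return OrthologCall(call.gene_a, call.gene_b, "unresolved", call.alternatives)
        chosen = cands[0] if s1 > s2 else cands[1]
    if cands[0] in pos_b or cands[1] in pos_b:
        return OrthologCall(call.gene_a, chosen, "resolved", call.alternatives)
    return OrthologCall(chosen, call.gene_b, "resolved", call.alternatives)


def outgroup_orthologs(
    families: dict[str, list[str]],
    ingroup_genes: dict[str, GeneModel],
    outgroup_genes: dict[str, GeneModel],
    hits: dict[tuple[str, str], float] | None = None,
) -> dict[str, str]:
    """family -> outgroup gene with the highest total similarity to the
    family's ingroup members (absent when nothing hits)."""
    totals: dict[str, dict[str, float]] = {}
    if hits is not None:
        member_fam = {m: f for f, members in families.items() for m in members}
        for (q, s), sc in hits.items():
            g_in, g_out = (q, s) if q in ingroup_genes else (s, q)
            if g_in not in ingroup_genes or g_out not in outgroup_genes:
                continue
            fam = member_fam.get(g_in)
            if fam is None:
                continue
            totals.setdefault(fam, defaultdict(float))[g_out] += sc
    else:
        for fam in sorted(families):
            members = [m for m in families[fam] if m in ingroup_genes]
            if not members:
                continue
            acc: dict[str, float] = defaultdict(float)
            for out_id, out_gene in outgroup_genes.items():
                for m in members:
                    sc = _score(ingroup_genes[m], out_gene)
                    if sc > 0:
                        acc[out_id] += sc
            if acc:
                totals[fam] = acc
    return {
        fam: max(sorted(acc), key=lambda g: acc[g])
        for fam, acc in totals.items()
        if acc
    }


# ---------------------------------------------------------------------------
# ortholog groups from gene trees


def groups_from_gene_tree(
    tree: dendropy.Tree | str,
    species_of,
) -> list[list[str]]:
    """Per-copy ortholog groups by stepwise extension from sister pairs.

    The tree is midpoint-rooted (for a WGD family the deepest split is the
    copy split). Each cherry of two different-species leaves seeds a
    group; walking rootward, unclaimed leaves joining next are absorbed
    when they add a new species; leaves duplicating a species already in
    the group are skipped. Genes are claimed by at most one group; seeds
    are processed in deterministic (smallest-member) order.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    tree = tree.clone(depth=1)
    try:
        tree.reroot_at_midpoint(update_bipartitions=False)
    except (AssertionError, ValueError):  # zero-length or degenerate trees
        pass
    tree.is_rooted = True

    cherries = []
    for node in tree.postorder_node_iter():
        kids = [k for k in node.child_nodes() if k.is_leaf()]
        if len(kids) < 2:
            continue
        labels = sorted(k.taxon.label for k in kids)
        for i, l1 in enumerate(labels):
            for l2 in labels[i + 1 :]:
                if species_of(l1) != species_of(l2):
                    cherries.append((l1, l2, node))
    cherries.sort(key=lambda c: (c[0], c[1]))

    claimed: set[str] = set()
    groups: list[list[str]] = []
    for l1, l2, node in cherries:
        if l1 in claimed or l2 in claimed:
            continue
        group = [l1, l2]
        species = {species_of(l1), species_of(l2)}
        claimed.update(group)
        # absorb the seed node's remaining leaf children, then walk rootward
        cur = node
        first = True
        while cur is not None:
            sibs = cur.child_nodes() if first else [
                s for s in cur.child_nodes() if s is not prev
            ]
            for sib in sibs:
                for leaf in sib.leaf_iter():
                    lab = leaf.taxon.label
                    sp = species_of(lab)
                    if lab not in claimed and sp not in species:
                        group.append(lab)
                        species.add(sp)
                        claimed.add(lab)
            prev, cur, first = cur, cur.parent_node, False
        groups.append(sorted(group))
    return groups


# ---------------------------------------------------------------------------
# paralogon graph and chains


@dataclass
class ParalogonChains:
    graph: nx.Graph
    chains: list[list[tuple[str, str]]] = field(default_factory=list)


def chain_paralogons(
    family_groups: dict[str, list[list[str]]],
    paralogon_of: dict[str, tuple[str, str]],
) -> ParalogonChains:
    """Greedy heaviest-edge chaining of paralogons across species.

    Edge weight between two paralogon nodes = number of gene trees
    (families) with an ortholog group linking them. Chains are disjoint:
    starting from the heaviest unused edge, both endpoints are extended
    along their heaviest compatible edges; each paralogon joins exactly
    one chain. Ties break lexicographically.
    """
    weights: dict[tuple, int] = defaultdict(int)
    for fam in sorted(family_groups):
        fam_edges = set()
        for group in family_groups[fam]:
            nodes = sorted({paralogon_of[g] for g in group if g in paralogon_of})
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    if nodes[i][0] != nodes[j][0]:  # different species only
                        fam_edges.add((nodes[i], nodes[j]))
        for e in fam_edges:
            weights[e] += 1

    graph = nx.Graph()
    for (u, v), w in weights.items():
        graph.add_edge(u, v, weight=w)

    edges = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    used: set[tuple[str, str]] = set()
    chains: list[list[tuple[str, str]]] = []

    def heaviest_extension(end, exclude):
        best = None
        for nb in graph.neighbors(end):
            if nb in used or nb in exclude:
                continue
            key = (-graph[end][nb]["weight"], nb)
            if best is None or key < best:
                best = key
        return best[1] if best else None

    for (u, v), w in edges:
        if u in used or v in used:
            continue
        chain = [u, v]
        used.update(chain)
        while True:
            nxt = heaviest_extension(chain[-1], set(chain))
            if nxt is None:
                break
            chain.append(nxt)
            used.add(nxt)
        while True:
            nxt = heaviest_extension(chain[0], set(chain))
            if nxt is None:
                break
            chain.insert(0, nxt)
            used.add(nxt)
        chains.append(chain)
    return ParalogonChains(graph=graph, chains=chains)
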