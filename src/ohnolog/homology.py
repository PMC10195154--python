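"""Similarity search, reciprocal best hits, families, gene trees, Ks/Ka.

Pairwise protein similarity uses exact global alignment (BLOSUM62, affine
gaps) behind a shared k-mer prefilter, so that only sequence pairs with at
least one shared k-mer are aligned; unrelated pairs return no hit. Ks and
Ka are estimated by Nei-Gojobori counting (pathway averaging over codon
substitution orders) with Jukes-Cantor multiple-hit correction.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from . import codons as C
from .models import DivergenceEstimate, GeneModel, HitScore

logger = logging.getLogger(__name__)

_AA = set("ACDEFGHIKLMNPQRSTVWY")

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


def _make_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = mode
    return aligner


_ALIGNER = _make_aligner()


def score_pair(protein_a: str, protein_b: str, ids: tuple[str, str] = ("a", "b")) -> HitScore:
    """Global affine-gap alignment score and identity of two proteins."""
    for seq in (protein_a, protein_b):
        if not seq:
            raise ValueError("empty protein sequence")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aln = _ALIGNER.align(protein_a, protein_b)[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return HitScore(ids[0], ids[1], float(aln.score), matches / len(a))


# ---------------------------------------------------------------------------
# k-mer prefilter + all-vs-all hits


def _kmer_index(genes: list[GeneModel], k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(genes):
        seen = set()
        for p in range(len(g.protein) - k + 1):
            kmer = g.protein[p : p + k]
            if kmer not in seen:
                index[kmer].append(i)
                seen.add(kmer)
    return index


def candidate_pairs(
    genes_a: list[GeneModel],
    genes_b: list[GeneModel] | None = None,
    k: int = 5,
    min_shared: int = 2,
) -> list[tuple[int, int]]:
    """Index pairs sharing >= ``min_shared`` k-mers. With ``genes_b=None``
    the within-set pairs (i < j) are returned."""
    within = genes_b is None
    if within:
        genes_b = genes_a
    idx_b = _kmer_index(genes_b, k)
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for i, g in enumerate(genes_a):
        seen = set()
        for p in range(len(g.protein) - k + 1):
            kmer = g.protein[p : p + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for j in idx_b.get(kmer, ()):
                if within and j <= i:
                    continue
                counts[(i, j)] += 1
    return sorted(p for p, c in counts.items() if c >= min_shared)


def all_vs_all_hits(
    genes_a: list[GeneModel],
    genes_b: list[GeneModel] | None = None,
    k: int = 5,
    min_shared: int = 2,
) -> list[HitScore]:
    """Alignment scores for all prefilter-passing pairs.

    Within one gene set (``genes_b=None``) both orientations of each pair
    are emitted so best-hit lookups are symmetric.
    """
    within = genes_b is None
    pairs = candidate_pairs(genes_a, genes_b, k=k, min_shared=min_shared)
    gb = genes_a if within else genes_b
    hits: list[HitScore] = []
    for i, j in pairs:
        a, b = genes_a[i], gb[j]
        aln = _ALIGNER.align(a.protein, b.protein)[0]
        if aln.score <= 0:  # unrelated pair that slipped through the prefilter
            continue
        s1, s2 = aln[0], aln[1]
        matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
        hit = HitScore(a.gene_id, b.gene_id, float(aln.score), matches / len(s1))
        hits.append(hit)
        if within:
            hits.append(HitScore(b.gene_id, a.gene_id, hit.score, hit.identity))
    return hits


def best_hits(hits: list[HitScore]) -> dict[str, str]:
    """query -> unique best subject; ties broken by lexicographic subject
    id (logged)."""
    best: dict[str, tuple[float, str]] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.score, _neg_lex(h.subject_id)) > (cur[0], _neg_lex(cur[1])):
            if cur is not None and h.score == cur[0]:
                logger.debug("best-hit tie for %s: %s vs %s", h.query_id, cur[1], h.subject_id)
            best[h.query_id] = (h.score, h.subject_id)
    return {q: s for q, (_, s) in best.items()}


class _neg_lex(str):
    """Ordering helper: higher rank for lexicographically smaller ids."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal_best_hits(
    genes_a: list[GeneModel], genes_b: list[GeneModel], k: int = 5, min_shared: int = 2
) -> list[tuple[str, str]]:
    """RBH pairs between two gene sets (two species, or one genome against
    itself when the sets are identical)."""
    if not genes_a or not genes_b:
        raise ValueError("gene sets must be nonempty")
    hits_ab = all_vs_all_hits(genes_a, genes_b, k=k, min_shared=min_shared)
    hits_ba = [HitScore(h.subject_id, h.query_id, h.score, h.identity) for h in hits_ab]
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.append((a, b))
    return sorted(pairs)


def within_genome_rbh(genes: list[GeneModel], k: int = 5, min_shared: int = 2) -> list[tuple[str, str]]:
    """Within-genome RBH paralog pairs (self-hits excluded), canonical order."""
    hits = all_vs_all_hits(genes, None, k=k, min_shared=min_shared)
    best = best_hits(hits)
    pairs = set()
    for a, b in best.items():
        if best.get(b) == a and a != b:
            pairs.add((a, b) if a < b else (b, a))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# gene families


def cluster_families(
    rbh_edges: list[tuple[str, str]],
    synteny_edges: list[tuple[str, str]] | None = None,
) -> dict[str, list[str]]:
    """Families = connected components of the RBH graph, optionally
    augmented with synteny-supported best-hit edges. Deterministic family
    ids assigned by the lexicographically smallest member."""
    g = nx.Graph()
    g.add_edges_from(rbh_edges)
    if synteny_edges:
        g.add_edges_from(synteny_edges)
    families: dict[str, list[str]] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        families[f"fam_{members[0]}"] = members
    return families


# ---------------------------------------------------------------------------
# Ks / Ka (Nei-Gojobori counting, Jukes-Cantor correction)


def _protein_guided_codons(cds_a: str, cds_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Codon arrays of both CDS restricted to aligned, ungapped columns."""
    for cds in (cds_a, cds_b):
        if len(cds) % 3:
            raise ValueError("CDS length must be a multiple of 3")
    ca, cb = C.encode_cds(cds_a), C.encode_cds(cds_b)
    if len(ca) == len(cb):
        return ca, cb
    pa, pb = C.translate(ca), C.translate(cb)
    aln = _ALIGNER.align(pa, pb)[0]
    ia = ib = 0
    keep_a, keep_b = [], []
    for x, y in zip(aln[0], aln[1]):
        if x != "-" and y != "-":
            keep_a.append(ia)
            keep_b.append(ib)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return ca[keep_a], cb[keep_b]


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p <= 0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def estimate_ks_ka(cds_a: str, cds_b: str) -> DivergenceEstimate:
    """Nei-Gojobori Ks/Ka for a (alignable) CDS pair.

    Sites are averaged between the two sequences; multi-base codon
    differences are averaged over substitution orderings, skipping paths
    through stop codons. ``saturated`` is set when the Jukes-Cantor
    correction is undefined for either class.
    """
    ca, cb = _protein_guided_codons(cds_a, cds_b)
    if len(ca) == 0:
        raise ValueError("no alignable codons")
    S = float((C.SYN_SITES[ca].sum() + C.SYN_SITES[cb].sum()) / 2.0)
    N = float((C.NONSYN_SITES[ca].sum() + C.NONSYN_SITES[cb].sum()) / 2.0)
    sd = nd = 0.0
    for i, j in zip(ca, cb):
        s, n = C.path_counts(int(i), int(j))
        sd += s
        nd += n
    ks, sat_s = _jc(sd / S) if S > 0 else (0.0, False)
    ka, sat_n = _jc(nd / N) if N > 0 else (0.0, False)
    ka_ks = None
    if ks > 0 and math.isfinite(ks) and math.isfinite(ka):
        ka_ks = ka / ks
    return DivergenceEstimate(ks=ks, ka=ka, ka_ks=ka_ks, saturated=sat_s or sat_n)


# ---------------------------------------------------------------------------
# gene trees (neighbor joining on protein p-distance)


def protein_p_distance(prot_a: str, prot_b: str) -> float:
    """Fraction of differing aligned (ungapped) positions."""
    if len(prot_a) == len(prot_b):
        diffs = sum(1 for x, y in zip(prot_a, prot_b) if x != y)
        return diffs / len(prot_a)
    aln = _ALIGNER.align(prot_a, prot_b)[0]
    pairs = [(x, y) for x, y in zip(aln[0], aln[1]) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def build_gene_tree(
    members: dict[str, str],
    distances: np.ndarray | None = None,
) -> str:
    """Unrooted NJ tree (newick) for a family.

    ``members`` maps leaf id -> protein sequence; a precomputed distance
    matrix (ordered by sorted leaf id) may be supplied instead of
    sequences. Families of size < 3 return the trivial topology.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = sorted(members)
    if len(ids) < 3:
        if len(ids) == 1:
            return f"({ids[0]});"
        return f"({ids[0]},{ids[1]});"
    if distances is None:
        n = len(ids)
        distances = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = protein_p_distance(members[ids[i]], members[ids[j]])
                distances[i, j] = distances[j, i] = d
    dm = DistanceMatrix(distances, ids)
    tree = nj(dm)
    return str(tree).strip()
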