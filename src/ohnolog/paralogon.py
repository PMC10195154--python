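"""Within-genome paralogon detection and ancestral gene-order reconstruction.

Anchors (within-genome RBH paralog pairs) are chained into colinear
paralogous blocks per scaffold pair, blocks are fused into paralogons, the
retention status of every locus inside the fused spans is called, and a
pre-WGD ancestral gene order is rebuilt by choosing one representative per
locus.

Chaining parameters: consecutive anchors may be at most ``max_gap`` ranks
apart on both scaffolds (a scanning window larger than the gap tolerance
adds nothing, so the classic window parameter is subsumed by ``max_gap``);
chains shorter than ``min_anchors`` are discarded; co-oriented blocks on
one scaffold pair are fused when separated by at most ``fuse_gap`` ranks,
and fused spans are extended outward by up to ``fuse_gap`` ranks so that
terminal single-copy loci are still assigned.
"""

from __future__ import annotations

import logging

import numpy as np

from .models import (
    AnchorPair,
    AncestralLocus,
    GeneModel,
    Paralogon,
    ParalogousBlock,
    PairStatus,
    RETAINED_BOTH,
    SINGLE_COPY,
)

logger = logging.getLogger(__name__)


def _positions(genome: list[GeneModel]) -> dict[str, tuple[str, int]]:
    return {g.gene_id: (g.scaffold, g.rank) for g in genome}


def find_anchors(
    genome: list[GeneModel],
    rbh_pairs: list[tuple[str, str]],
    divergence: dict[tuple[str, str], object] | None = None,
) -> list[AnchorPair]:
    """Within-genome WGD anchor candidates from RBH paralog pairs."""
    anchors = []
    for a, b in rbh_pairs:
        if a == b:
            continue
        a, b = (a, b) if a < b else (b, a)
        div = divergence.get((a, b)) if divergence else None
        anchors.append(AnchorPair(a, b, div))
    return sorted(anchors, key=lambda x: (x.gene1_id, x.gene2_id))


def merge_blocks(
    anchors: list[AnchorPair],
    genome: list[GeneModel],
    min_anchors: int = 3,
    max_gap: int = 5,
    extra_pairs: list[tuple[str, str]] | None = None,
) -> list[ParalogousBlock]:
    """Chain colinear anchors into paralogous blocks, then extend the
    blocks with non-RBH syntenic matches falling inside the block spans."""
    pos = _positions(genome)
    by_pair: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for anc in anchors:
        (s1, r1), (s2, r2) = pos[anc.gene1_id], pos[anc.gene2_id]
        if s1 == s2:
            continue  # tandem/intra-scaffold pair: never a WGD block anchor
        if s2 < s1:
            s1, s2, r1, r2 = s2, s1, r2, r1
            anc = AnchorPair(anc.gene1_id, anc.gene2_id, anc.divergence)
            key_swap = True
        else:
            key_swap = False
        by_pair.setdefault((s1, s2), []).append((r1, r2, anc))
        _ = key_swap

    blocks: list[ParalogousBlock] = []
    for (s1, s2), items in sorted(by_pair.items()):
        items.sort()
        chain: list[tuple[int, int, AnchorPair]] = []
        orient = 0

        def flush():
            nonlocal chain, orient
            if len(chain) >= min_anchors:
                r1s = [r for r, _, _ in chain]
                r2s = [r for _, r, _ in chain]
                blocks.append(
                    ParalogousBlock(
                        scaffold1=s1,
                        scaffold2=s2,
                        span1=(min(r1s), max(r1s)),
                        span2=(min(r2s), max(r2s)),
                        anchors=[a for _, _, a in chain],
                        orientation=orient if orient else 1,
                    )
                )
            chain = []
            orient = 0

        for r1, r2, anc in items:
            if not chain:
                chain.append((r1, r2, anc))
                continue
            p1, p2, _ = chain[-1]
            step2 = r2 - p2
            ok = 0 < r1 - p1 <= max_gap + 1 and 0 < abs(step2) <= max_gap + 1
            if ok and len(chain) == 1:
                orient = 1 if step2 > 0 else -1
            elif ok and ((step2 > 0) != (orient > 0)):
                ok = False
            if ok:
                chain.append((r1, r2, anc))
            else:
                flush()
                chain.append((r1, r2, anc))
        flush()

    # extension with non-RBH syntenic matches
    if extra_pairs:
        anchor_set = {(b.gene1_id, b.gene2_id) for blk in blocks for b in blk.anchors}
        for blk in blocks:
            lo1, hi1 = blk.span1
            lo2, hi2 = blk.span2
            for a, b in extra_pairs:
                a, b = (a, b) if a < b else (b, a)
                if (a, b) in anchor_set or a not in pos or b not in pos:
                    continue
                (sa, ra), (sb, rb) = pos[a], pos[b]
                if sa == blk.scaffold1 and sb == blk.scaffold2:
                    pass
                elif sb == blk.scaffold1 and sa == blk.scaffold2:
                    a, b, ra, rb = b, a, rb, ra
                else:
                    continue
                if lo1 <= ra <= hi1 and lo2 <= rb <= hi2:
                    blk.syntenic_additions.append((a, b))
    return blocks


def fuse_paralogons(blocks: list[ParalogousBlock], fuse_gap: int = 10) -> list[Paralogon]:
    """Concatenate co-oriented adjacent blocks on one scaffold pair."""
    by_pair: dict[tuple[str, str], list[ParalogousBlock]] = {}
    for b in blocks:
        by_pair.setdefault((b.scaffold1, b.scaffold2), []).append(b)
    paralogons: list[Paralogon] = []
    for (s1, s2), blks in sorted(by_pair.items()):
        blks.sort(key=lambda b: b.span1)
        current: list[ParalogousBlock] = []
        for b in blks:
            if (
                current
                and b.orientation == current[-1].orientation
                and 0 <= b.span1[0] - current[-1].span1[1] <= fuse_gap + 1
                and (
                    abs(b.span2[0] - current[-1].span2[1]) <= fuse_gap + 1
                    or abs(current[-1].span2[0] - b.span2[1]) <= fuse_gap + 1
                )
            ):
                current.append(b)
            else:
                if current:
                    paralogons.append(_make_paralogon(s1, s2, current))
                current = [b]
        if current:
            paralogons.append(_make_paralogon(s1, s2, current))
    for i, p in enumerate(sorted(paralogons, key=lambda p: (p.scaffold1, p.scaffold2, p.span1))):
        p.paralogon_id = f"par{i:03d}"
    return sorted(paralogons, key=lambda p: p.paralogon_id)


def _make_paralogon(s1: str, s2: str, blks: list[ParalogousBlock]) -> Paralogon:
    return Paralogon(paralogon_id="", scaffold1=s1, scaffold2=s2, blocks=list(blks))


def call_statuses(
    paralogons: list[Paralogon],
    genome: list[GeneModel],
    pairs: list[tuple[str, str]] | None = None,
    span_extend: int = 10,
) -> None:
    """Fill each paralogon's per-locus status list.

    ``pairs`` are retained-pair candidates (defaults to the paralogons'
    anchors plus syntenic additions). Each pair becomes one RETAINED_BOTH
    locus of the paralogon that holds both its genes, or — for pairs split
    by gene relocation — the paralogon holding one of them. Any other gene
    lying inside the (extended) span of either scaffold is a SINGLE_COPY
    locus. Every gene is assigned to at most one locus. Loci are ordered
    along scaffold1, interpolating scaffold2-only loci through the anchor
    rank mapping.
    """
    pos = _positions(genome)
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genome:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for lst in by_scaffold.values():
        lst.sort(key=lambda g: g.rank)

    plist = sorted(paralogons, key=lambda p: p.paralogon_id)
    spans: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    for par in plist:
        (a0, a1), (b0, b1) = par.span1, par.span2
        spans[par.paralogon_id] = (
            (a0 - span_extend, a1 + span_extend),
            (b0 - span_extend, b1 + span_extend),
        )

    def side_in_span(par: Paralogon, gid: str) -> int:
        """1/2 if the gene lies in the paralogon's scaffold1/2 span, else 0."""
        s, r = pos[gid]
        (lo1, hi1), (lo2, hi2) = spans[par.paralogon_id]
        if s == par.scaffold1 and lo1 <= r <= hi1:
            return 1
        if s == par.scaffold2 and lo2 <= r <= hi2:
            return 2
        return 0

    if pairs is None:
        pairs = []
        for par in plist:
            for blk in par.blocks:
                pairs.extend((a.gene1_id, a.gene2_id) for a in blk.anchors)
                pairs.extend(blk.syntenic_additions)
    pairs = sorted({tuple(sorted(p)) for p in pairs})

    # place each pair in the best-matching paralogon
    placed: dict[str, list[tuple[str, str, str]]] = {p.paralogon_id: [] for p in plist}
    claimed: set[str] = set()
    for ga, gb in pairs:
        if ga in claimed or gb in claimed or ga not in pos or gb not in pos:
            continue
        if pos[ga][0] == pos[gb][0] and abs(pos[ga][1] - pos[gb][1]) <= 5:
            continue  # tandem pair (adjacent duplicate): never an ohnolog
            # locus; distant same-scaffold pairs can be relocated ohnologs
        best: tuple[int, str] | None = None
        for par in plist:
            ia, ib = side_in_span(par, ga), side_in_span(par, gb)
            if ia and ib and ia != ib:
                rank = 0  # both genes inside, on opposite scaffolds
            elif ia or ib:
                rank = 1  # relocated partner
            else:
                continue
            key = (rank, par.paralogon_id)
            if best is None or key < best:
                best = key
        if best is None:
            continue
        placed[best[1]].append((ga, gb, "both"))
        claimed.update((ga, gb))

    for par in plist:
        (lo1, hi1), (lo2, hi2) = spans[par.paralogon_id]
        map_pts = sorted(
            (pos[b][1], pos[a][1])
            for a, b, _ in placed[par.paralogon_id]
            if pos[a][0] == par.scaffold1 and pos[b][0] == par.scaffold2
        )

        def interp(r2: int) -> float:
            if not map_pts:
                return float(r2)
            return float(np.interp(r2, [x for x, _ in map_pts], [y for _, y in map_pts]))

        entries: list[tuple[float, int, str, str | None, str | None]] = []
        for ga, gb, _ in placed[par.paralogon_id]:
            if pos[ga][0] == par.scaffold1:
                g1, g2 = ga, gb
            elif pos[gb][0] == par.scaffold1:
                g1, g2 = gb, ga
            elif pos[ga][0] == par.scaffold2:
                g1, g2 = gb, ga  # relocated partner fills the scaffold1 slot
            else:
                g1, g2 = ga, gb
            key = float(pos[g1][1]) if pos[g1][0] == par.scaffold1 else interp(pos[g2][1])
            entries.append((key, 0, "both", g1, g2))
        for g in by_scaffold.get(par.scaffold1, []):
            if g.gene_id not in claimed and lo1 <= g.rank <= hi1:
                entries.append((float(g.rank), 1, "single1", g.gene_id, None))
                claimed.add(g.gene_id)
        for g in by_scaffold.get(par.scaffold2, []):
            if g.gene_id not in claimed and lo2 <= g.rank <= hi2:
                entries.append((interp(g.rank), 2, "single2", None, g.gene_id))
                claimed.add(g.gene_id)

        entries.sort(key=lambda e: (e[0], e[1], e[3] or "", e[4] or ""))
        statuses = []
        for idx, (_, _, kind, g1, g2) in enumerate(entries):
            locus_id = f"{par.paralogon_id}:{idx:04d}"
            if kind == "both":
                statuses.append(PairStatus(locus_id, RETAINED_BOTH, g1, g2))
            else:
                statuses.append(PairStatus(locus_id, SINGLE_COPY, g1, g2))
        par.statuses = statuses


def gene_assignments(paralogons: list[Paralogon]) -> dict[str, str]:
    """gene_id -> paralogon_id over all called loci."""
    out: dict[str, str] = {}
    for par in paralogons:
        for st in par.statuses:
            for g in st.surviving():
                out[g] = par.paralogon_id
    return out


def retention_fraction(paralogons: list[Paralogon]) -> float:
    """retained_both / total loci across paralogons."""
    both = sum(1 for p in paralogons for s in p.statuses if s.status == RETAINED_BOTH)
    total = sum(len(p.statuses) for p in paralogons)
    return both / total if total else float("nan")


def reconstruct_ancestor(paralogons: list[Paralogon], seed: int = 0) -> list[AncestralLocus]:
    """One representative gene per locus, ordered along the paralogons.

    Both-retained loci pick a random copy with the given seed (repeat with
    the reconstructed genome to peel older duplication rounds)."""
    rng = np.random.default_rng(seed)
    loci: list[AncestralLocus] = []
    order = 0
    for par in sorted(paralogons, key=lambda p: p.paralogon_id):
        for st in par.statuses:
            if st.status == RETAINED_BOTH:
                rep = st.gene1_id if rng.random() < 0.5 else st.gene2_id
            else:
                rep = st.gene1_id or st.gene2_id
            loci.append(AncestralLocus(st.locus_id, rep, order))
            order += 1
    return loci


def detect_paralogons(
    genome: list[GeneModel],
    rbh_pairs: list[tuple[str, str]],
    extra_pairs: list[tuple[str, str]] | None = None,
    min_anchors: int = 3,
    max_gap: int = 5,
    fuse_gap: int = 10,
    span_extend: int = 10,
) -> list[Paralogon]:
    """Convenience wrapper: anchors -> blocks -> paralogons -> statuses.

    RBH pairs double as the retained-pair candidates for status calling,
    so anchors dropped from chains (or split by relocation) are still
    counted as one locus; ``extra_pairs`` adds non-RBH syntenic matches.
    """
    anchors = find_anchors(genome, rbh_pairs)
    blocks = merge_blocks(anchors, genome, min_anchors=min_anchors, max_gap=max_gap,
                          extra_pairs=extra_pairs or rbh_pairs)
    paralogons = fuse_paralogons(blocks, fuse_gap=fuse_gap)
    all_pairs = list(rbh_pairs) + list(extra_pairs or [])
    call_statuses(paralogons, genome, pairs=all_pairs, span_extend=span_extend)
    return paralogons
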