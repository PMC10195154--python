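"""Forward simulator of post-whole-genome-duplication genome evolution.

The generator produces the inputs the analysis pipeline consumes — per
species CDS/protein sequences, gene positions, expression tables, a species
tree — together with a complete ground-truth record (loss branches, lost
copies, conversion tracts, single-gene duplications, translocations) used
to validate every downstream stage.

Model sketch
------------
A pre-WGD ancestor of ``n_genes`` genes on ``n_scaffolds`` scaffolds is
doubled by a single WGD at the ingroup root. Along every branch (lengths in
expected synonymous substitutions per site, "Ks units"):

* each still-duplicated pair loses one copy with hazard
  ``h = base_loss_rate * exp(-expression_beta * centred log10 FPKM)
  * category_effect``; the lost copy is chosen by a logistic function of
  the current expression log-ratio between the copies, which performs a
  Brownian walk at rate ``predetermination_drift`` (the "predetermination"
  mechanism: the lower-expressed copy carries the larger hazard share);
* synonymous and nonsynonymous substitutions accrue as Poisson processes
  with Ka/Ks = ``omega``;
* gene-conversion tracts overwrite a contiguous run of loci in one copy
  with the other, resetting their divergence;
* rare single-gene duplications copy one gene in place;
* translocations move single genes to random positions.

Outgroup lineages diverge below the WGD node and stay single-copy.
"""

from __future__ import annotations

import copy as _copy
import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import codons as C
from .models import GeneModel, ONE

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "generate_species_tree",
    "generate_ancestral_genome",
    "apply_wgd",
    "simulate",
    "write_dataset",
    "read_dataset",
    "presence_matrix_from_truth",
    "base_pair_id",
    "copy_label",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


_DEFAULT_CATEGORY_EFFECTS = (0.4, 0.6, 0.8, 1.0, 1.0, 1.2, 1.4, 1.6)


@dataclass
class SimConfig:
    """Parameters of the forward simulation (see module docstring).

    Defaults emulate the recent *Paramecium aurelia* WGD: a 13-species
    ingroup radiating shortly after the duplication plus two pre-WGD
    outgroups, tree depth 0.5 Ks units per copy (ohnolog Ks ~ 1), and a
    pair-loss hazard giving ~52% median retention at the leaves.
    """

    n_genes: int = 1000
    n_scaffolds: int = 10
    n_ingroup: int = 13
    n_outgroup: int = 2
    depth: float = 0.5
    wgd_stem: float = 0.1  # Ks between the WGD and the first speciation
    tree_newick: str | None = None
    radiation_shape: float = 1.5  # Beta(1, shape): larger = splits closer to the WGD
    base_loss_rate: float = 1.1  # pair-loss hazard per unit Ks
    expression_beta: float = 0.4  # hazard multiplier exp(-beta * centred log10 FPKM)
    n_categories: int = 8
    category_effects: tuple[float, ...] | None = _DEFAULT_CATEGORY_EFFECTS
    predetermination_drift: float = 0.8  # sd of copy log10-expression ratio per sqrt(Ks)
    asymmetry_strength: float = 3.0  # logistic slope: expression ratio -> loss share
    expression_drift: float = 0.3  # sd of pair mean log10 expression per sqrt(Ks)
    expression_mu: float = 2.0  # ln-FPKM mean of the ancestral lognormal
    expression_sigma: float = 1.5
    conversion_rate: float = 0.05  # tract initiations per scaffold pair per unit Ks
    conversion_tract_len: float = 8.0  # mean loci per tract (geometric)
    sgd_rate: float = 5e-4  # single-gene duplications per gene per unit Ks
    translocation_rate: float = 0.01  # moves per gene per unit Ks
    omega: float = 0.05  # Ka/Ks of the substitution process
    rate_variation: float = 0.0  # lognormal sigma of per-branch rate multipliers
    min_codons: int = 150
    max_codons: int = 450
    evolve_sequences: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < self.n_scaffolds or self.n_scaffolds < 1:
            raise ConfigError("need n_genes >= n_scaffolds >= 1")
        if self.n_ingroup < 2:
            raise ConfigError("n_ingroup must be >= 2")
        if self.n_outgroup < 0:
            raise ConfigError("n_outgroup must be >= 0")
        for name in (
            "depth",
            "wgd_stem",
            "base_loss_rate",
            "predetermination_drift",
            "expression_drift",
            "conversion_rate",
            "sgd_rate",
            "translocation_rate",
            "omega",
            "rate_variation",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.category_effects is not None:
            if len(self.category_effects) != self.n_categories:
                raise ConfigError("category_effects length must equal n_categories")
            if any(e <= 0 for e in self.category_effects):
                raise ConfigError("hazard multipliers must be > 0")

    def categories(self) -> list[str]:
        return [f"cat{i+1:02d}" for i in range(self.n_categories)]


_BASE_ID_RE = re.compile(r"(g\d+)([AB])?")


def base_pair_id(gene_id: str) -> str | None:
    """Ancestral pair id encoded in a simulated gene id, or None."""
    m = _BASE_ID_RE.search(gene_id)
    return m.group(1) if m else None


def copy_label(gene_id: str) -> str | None:
    """WGD copy label ('A'/'B') encoded in a simulated gene id."""
    if ".s" in gene_id:  # single-gene duplicate: not a WGD copy
        return None
    m = _BASE_ID_RE.search(gene_id)
    return m.group(2) if m else None


# ---------------------------------------------------------------------------
# species tree


def generate_species_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Random ultrametric species tree in Ks units.

    The ingroup radiates from the WGD node (labelled ``"wgd"``) with split
    times skewed toward the duplication (rapid post-WGD radiation);
    outgroup lineages attach below the WGD node at intervals of
    ``depth / 2``. With ``rate_variation > 0`` every branch length is
    multiplied by an i.i.d. lognormal rate factor (mean 1), making
    realized divergence vary across lineages.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.tree_newick is not None:
        tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick", preserve_underscores=True)
        tree.is_rooted = True
        _label_internal(tree)
        return tree
    n, depth = cfg.n_ingroup, cfg.depth

    # forward construction: node = [label, time, children]
    split_times = [0.0] + sorted(
        (depth * 0.95 * rng.beta(1.0, cfg.radiation_shape, size=n - 2)).tolist()
    )
    root = ["", 0.0, []]
    active = [root]
    for t in split_times:
        node = active.pop(int(rng.integers(len(active)))) if len(active) > 1 else active.pop(0)
        node[1] = t
        kids = [["", depth, []], ["", depth, []]]
        node[2] = kids
        active.extend(kids)
    leaf_names = [f"sp{i+1:02d}" for i in range(n)]
    rng.shuffle(leaf_names)
    it = iter(leaf_names)

    def to_newick(node, parent_time):
        if not node[2]:
            return f"{next(it)}:{depth - parent_time:.8f}"
        inner = ",".join(to_newick(k, node[1]) for k in node[2])
        return f"({inner}):{node[1] - parent_time:.8f}"

    nwk = to_newick(root, 0.0)
    # chain outgroups below the WGD node
    for i in range(cfg.n_outgroup):
        stem = 0.5 * depth
        out_len = depth + (i + 1) * stem
        nwk = f"({nwk},out{i+1:02d}:{out_len:.8f}):{stem:.8f}"
    tree = dendropy.Tree.get(data=nwk + ";", schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    if cfg.rate_variation > 0:
        sig = cfg.rate_variation
        for edge in tree.preorder_edge_iter():
            if edge.length:
                edge.length *= float(rng.lognormal(-sig * sig / 2.0, sig))
    _label_internal(tree)
    return tree


def _label_internal(tree: dendropy.Tree) -> None:
    """Deterministic internal-node labels; the ingroup MRCA is 'wgd'."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    ingroup = [l for l in leaves if not l.startswith("out")]
    if len(ingroup) >= 2:
        mrca = tree.mrca(taxon_labels=ingroup)
    else:
        mrca = tree.seed_node
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif node is mrca:
            node.label = "wgd"
        else:
            node.label = f"n{i:02d}"
            i += 1


def node_distance_from(tree: dendropy.Tree, origin_label: str) -> dict[str, float]:
    """Path length (Ks units) from the node labelled *origin_label* to every
    node at or below it."""
    origin = next(n for n in tree.preorder_node_iter() if n.label == origin_label)
    dist = {origin.label: 0.0}
    stack = [origin]
    while stack:
        node = stack.pop()
        for ch in node.child_nodes():
            dist[ch.label] = dist[node.label] + (ch.edge.length or 0.0)
            stack.append(ch)
    return dist


# ---------------------------------------------------------------------------
# ancestral genome and WGD


def generate_ancestral_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Pre-WGD ancestor: random stop-free CDS, lognormal FPKM, flat
    category labels with equal proportions."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_genes, cfg.n_scaffolds
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    fpkm = rng.lognormal(cfg.expression_mu, cfg.expression_sigma, size=n)
    cats = rng.integers(cfg.n_categories, size=n)
    non_stop = np.array(C.NON_STOP)
    genes: list[GeneModel] = []
    gi = 0
    for si, size in enumerate(sizes):
        for r in range(size):
            length = int(rng.integers(cfg.min_codons, cfg.max_codons + 1))
            arr = non_stop[rng.integers(len(non_stop), size=length)]
            cds = C.decode_cds(arr)
            genes.append(
                GeneModel(
                    gene_id=f"g{gi:05d}",
                    species="anc",
                    scaffold=f"scf{si+1:02d}",
                    rank=r,
                    cds=cds,
                    protein=C.translate(arr),
                    fpkm=float(fpkm[gi]),
                    category=cfg.categories()[cats[gi]],
                )
            )
            gi += 1
    return genes


def apply_wgd(genome: list[GeneModel]) -> tuple[list[GeneModel], dict[str, tuple[str, str]]]:
    """Duplicate every gene; copy B goes on a mirrored scaffold with the
    same gene order. Returns (doubled genome, pair -> (copyA, copyB))."""
    if not genome:
        raise ValueError("genome must be nonempty")
    doubled: list[GeneModel] = []
    anchors: dict[str, tuple[str, str]] = {}
    for g in genome:
        a = GeneModel(
            g.gene_id + "A", g.species, g.scaffold + "A", g.rank, g.strand,
            g.cds, g.protein, g.fpkm, g.category,
        )
        b = GeneModel(
            g.gene_id + "B", g.species, g.scaffold + "B", g.rank, g.strand,
            g.cds, g.protein, g.fpkm, g.category,
        )
        doubled.extend([a, b])
        anchors[g.gene_id] = (a.gene_id, b.gene_id)
    return doubled, anchors


# ---------------------------------------------------------------------------
# truth containers


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the simulated dataset."""

    config: SimConfig
    newick: str
    pair_ids: list[str]
    anchor: dict[str, tuple[str, str]]
    pair_scaffold: dict[str, str]  # ancestral scaffold of each pair
    leaf_states: pd.DataFrame  # pairs x species: 'BOTH' | 'A' | 'B'
    leaf_expression: dict[str, dict[str, float]]  # species -> gene base id -> log10 FPKM
    events: list[dict] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.leaf_states.columns)

    def loss_events(self) -> pd.DataFrame:
        rows = [e for e in self.events if e["type"] == "loss"]
        return pd.DataFrame(rows, columns=["type", "branch", "pair", "copy", "time"])

    def replay_leaf_states(self, tree: dendropy.Tree) -> pd.DataFrame:
        """Re-derive per-leaf states from the event list (validation)."""
        states = {}

        def walk(node, state):
            state = dict(state)
            for e in self.events:
                if e["type"] == "loss" and e["branch"] == node.label:
                    state[e["pair"]] = "B" if e["copy"] == "A" else "A"
            if node.is_leaf():
                if not node.taxon.label.startswith("out"):
                    states[node.taxon.label] = state
            for ch in node.child_nodes():
                walk(ch, state)

        wgd = next(n for n in tree.preorder_node_iter() if n.label == "wgd")
        start = {p: "BOTH" for p in self.pair_ids}
        for e in self.events:  # shared stem between the WGD and the MRCA
            if e["type"] == "loss" and e["branch"] == "wgd_stem":
                start[e["pair"]] = "B" if e["copy"] == "A" else "A"
        walk(wgd, start)
        df = pd.DataFrame(states).loc[self.pair_ids]
        return df[sorted(df.columns)]


# ---------------------------------------------------------------------------
# the forward process


class _Lineage:
    """Mutable per-lineage state, copied at speciations."""

    __slots__ = ("state", "m", "d", "seqs", "order", "sgd_meta", "post_wgd")

    def __init__(self):
        self.state: np.ndarray | None = None  # 0 both, 1 only A, 2 only B
        self.m: np.ndarray | None = None  # pair mean log10 FPKM
        self.d: np.ndarray | None = None  # log10 FPKM (A) - log10 FPKM (B)
        self.seqs: dict[str, np.ndarray] | None = None
        self.order: dict[str, list[str]] = {}
        self.sgd_meta: dict[str, dict] = {}
        self.post_wgd: bool = False

    def clone(self) -> "_Lineage":
        ln = _Lineage()
        ln.state = None if self.state is None else self.state.copy()
        ln.m = self.m.copy()
        ln.d = None if self.d is None else self.d.copy()
        ln.seqs = None if self.seqs is None else {k: v.copy() for k, v in self.seqs.items()}
        ln.order = {k: list(v) for k, v in self.order.items()}
        ln.sgd_meta = _copy.deepcopy(self.sgd_meta)
        ln.post_wgd = self.post_wgd
        return ln


class _Simulator:
    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.tree = generate_species_tree(cfg, self.rng)
        self.ancestor = generate_ancestral_genome(cfg, self.rng)
        self.n = len(self.ancestor)
        self.pair_ids = [g.gene_id for g in self.ancestor]
        self.pair_scaffold = {g.gene_id: g.scaffold for g in self.ancestor}
        self.pair_index = {p: i for i, p in enumerate(self.pair_ids)}
        self.categories = {g.gene_id: g.category for g in self.ancestor}
        e0 = np.log10(np.array([g.fpkm for g in self.ancestor]))
        cat_idx = np.array(
            [int(g.category[3:]) - 1 for g in self.ancestor]
        )
        eff = (
            np.asarray(cfg.category_effects)[cat_idx]
            if cfg.category_effects is not None
            else np.ones(self.n)
        )
        self.hazard = cfg.base_loss_rate * np.exp(-cfg.expression_beta * (e0 - e0.mean())) * eff
        self.e0 = e0
        self.events: list[dict] = []
        self.leaf_states: dict[str, np.ndarray] = {}
        self.leaf_expr: dict[str, dict[str, float]] = {}
        self.leaf_genomes: dict[str, list[GeneModel]] = {}
        self._sgd_counter = 0

    # ----- sequence helpers ------------------------------------------------

    def _evolve_seq(self, arr: np.ndarray, t: float) -> None:
        """In-place Poisson substitution process over time t (Ks units)."""
        if t <= 0:
            return
        rng = self.rng
        syn_w = C.SYN_SITES[arr]
        S = float(syn_w.sum())
        n_syn = rng.poisson(t * S) if S > 0 else 0
        for _ in range(n_syn):
            w = C.SYN_SITES[arr]
            tot = w.sum()
            if tot <= 0:
                break
            pos = int(rng.choice(len(arr), p=w / tot))
            alts = C.SYN_ALTS[arr[pos]]
            arr[pos] = alts[int(rng.integers(len(alts)))]
        N = float(C.NONSYN_SITES[arr].sum())
        n_non = rng.poisson(self.cfg.omega * t * N) if N > 0 else 0
        for _ in range(n_non):
            w = C.NONSYN_SITES[arr]
            tot = w.sum()
            if tot <= 0:
                break
            pos = int(rng.choice(len(arr), p=w / tot))
            alts = C.NONSYN_ALTS[arr[pos]]
            if not alts:
                continue
            arr[pos] = alts[int(rng.integers(len(alts)))]

    # ----- branch step -----------------------------------------------------

    def _branch(self, ln: _Lineage, t: float, label: str) -> None:
        cfg, rng = self.cfg, self.rng
        if t <= 0:
            return
        ln.m += rng.normal(0.0, cfg.expression_drift * math.sqrt(t), size=self.n)
        seq_clock: dict[str, float] = {}

        def ensure(gid: str, upto: float) -> None:
            if ln.seqs is None or gid not in ln.seqs:
                return
            done = seq_clock.get(gid, 0.0)
            if upto > done:
                self._evolve_seq(ln.seqs[gid], upto - done)
                seq_clock[gid] = upto

        if not ln.post_wgd:
            # single-copy pre-WGD lineage: substitutions + expression only
            if ln.seqs is not None:
                for gid in list(ln.seqs):
                    self._evolve_seq(ln.seqs[gid], t)
            return

        # --- copy loss -----------------------------------------------------
        both = np.flatnonzero(ln.state == 0)
        if both.size and cfg.base_loss_rate > 0:
            h = self.hazard[both]
            ltime = rng.exponential(1.0, size=both.size) / np.maximum(h, 1e-300)
            lost = ltime < t
            tau = np.minimum(ltime, t)
            if cfg.predetermination_drift > 0:
                ln.d[both] += rng.normal(size=both.size) * cfg.predetermination_drift * np.sqrt(tau)
            for j in np.flatnonzero(lost):
                i = both[j]
                p_lose_a = 1.0 / (1.0 + math.exp(cfg.asymmetry_strength * ln.d[i]))
                which = "A" if rng.random() < p_lose_a else "B"
                ln.state[i] = 2 if which == "A" else 1
                pid = self.pair_ids[i]
                gid = pid + which
                self.events.append(
                    {"type": "loss", "branch": label, "pair": pid,
                     "copy": which, "time": float(ltime[j])}
                )
                if ln.seqs is not None and gid in ln.seqs:
                    del ln.seqs[gid]
                    for lst in ln.order.values():  # may have been translocated
                        if gid in lst:
                            lst.remove(gid)
                            break
        elif both.size and cfg.predetermination_drift > 0:
            ln.d[both] += rng.normal(size=both.size) * cfg.predetermination_drift * math.sqrt(t)

        if ln.seqs is None:
            return

        # --- gene conversion ----------------------------------------------
        scafs = sorted({s for s in self.pair_scaffold.values()})
        for sc in scafs:
            n_ev = rng.poisson(cfg.conversion_rate * t)
            for _ in range(n_ev):
                u = float(rng.uniform(0, t))
                loci = [p for p in self.pair_ids if self.pair_scaffold[p] == sc]
                start = int(rng.integers(len(loci)))
                length = 1 + int(rng.geometric(1.0 / cfg.conversion_tract_len))
                tract = loci[start : start + length]
                donor_is_a = bool(rng.random() < 0.5)
                converted = []
                for pid in tract:
                    i = self.pair_index[pid]
                    if ln.state[i] != 0:
                        continue
                    src = pid + ("A" if donor_is_a else "B")
                    dst = pid + ("B" if donor_is_a else "A")
                    ensure(src, u)
                    ensure(dst, u)
                    ln.seqs[dst][:] = ln.seqs[src]
                    converted.append(pid)
                if converted:
                    self.events.append(
                        {"type": "conversion", "branch": label, "scaffold": sc,
                         "pairs": converted, "donor": "A" if donor_is_a else "B",
                         "time": u}
                    )

        # --- single-gene duplication --------------------------------------
        n_cur = len(ln.seqs)
        n_sgd = rng.poisson(cfg.sgd_rate * n_cur * t)
        for _ in range(n_sgd):
            u = float(rng.uniform(0, t))
            src = sorted(ln.seqs)[int(rng.integers(len(ln.seqs)))]
            ensure(src, u)
            self._sgd_counter += 1
            new = f"{src}.s{self._sgd_counter}"
            ln.seqs[new] = ln.seqs[src].copy()
            seq_clock[new] = u
            # insert next to the source gene
            for sc, lst in ln.order.items():
                if src in lst:
                    lst.insert(lst.index(src) + 1, new)
                    break
            base = base_pair_id(src)
            ln.sgd_meta[new] = {
                "source": src,
                "m": float(ln.m[self.pair_index[base]]),
                "category": self.categories[base],
            }
            self.events.append(
                {"type": "sgd", "branch": label, "source": src, "gene": new, "time": u}
            )

        # --- finish sequence evolution ------------------------------------
        for gid in list(ln.seqs):
            ensure(gid, t)

        # --- translocation -------------------------------------------------
        n_tr = rng.poisson(cfg.translocation_rate * len(ln.seqs) * t)
        for _ in range(n_tr):
            gid = sorted(ln.seqs)[int(rng.integers(len(ln.seqs)))]
            src_sc = next(sc for sc, lst in ln.order.items() if gid in lst)
            ln.order[src_sc].remove(gid)
            dst_sc = sorted(ln.order)[int(rng.integers(len(ln.order)))]
            pos = int(rng.integers(len(ln.order[dst_sc]) + 1))
            ln.order[dst_sc].insert(pos, gid)
            self.events.append(
                {"type": "translocation", "branch": label, "gene": gid,
                 "to_scaffold": dst_sc, "position": pos}
            )

    # ----- WGD at a node ---------------------------------------------------

    def _do_wgd(self, ln: _Lineage) -> None:
        ln.post_wgd = True
        ln.state = np.zeros(self.n, dtype=np.int8)
        ln.d = np.zeros(self.n)
        if ln.seqs is not None:
            new_seqs: dict[str, np.ndarray] = {}
            order: dict[str, list[str]] = {}
            for sc, lst in ln.order.items():
                order[sc + "A"] = [g + "A" for g in lst]
                order[sc + "B"] = [g + "B" for g in lst]
            for gid, arr in ln.seqs.items():
                new_seqs[gid + "A"] = arr.copy()
                new_seqs[gid + "B"] = arr.copy()
            ln.seqs = new_seqs
            ln.order = order

    # ----- leaf emission ---------------------------------------------------

    def _emit_leaf(self, ln: _Lineage, species: str) -> None:
        cfg = self.cfg
        if not ln.post_wgd:  # outgroup
            expr = {self.pair_ids[i]: float(ln.m[i]) for i in range(self.n)}
        else:
            self.leaf_states[species] = ln.state.copy()
            expr = {}
            for i, pid in enumerate(self.pair_ids):
                ea, eb = ln.m[i] + ln.d[i] / 2.0, ln.m[i] - ln.d[i] / 2.0
                if ln.state[i] in (0, 1):
                    expr[pid + "A"] = float(ea)
                if ln.state[i] in (0, 2):
                    expr[pid + "B"] = float(eb)
        self.leaf_expr[species] = expr

        if ln.seqs is None:
            return
        genes: list[GeneModel] = []
        for sc in sorted(ln.order):
            for rank, gid in enumerate(ln.order[sc]):
                base = base_pair_id(gid)
                arr = ln.seqs[gid]
                if gid in ln.sgd_meta:
                    fp = 10.0 ** ln.sgd_meta[gid]["m"]
                    cat = ln.sgd_meta[gid]["category"]
                else:
                    fp = 10.0 ** expr[gid if ln.post_wgd else base]
                    cat = self.categories[base]
                genes.append(
                    GeneModel(
                        gene_id=f"{species}_{gid}",
                        species=species,
                        scaffold=f"{species}_{sc}",
                        rank=rank,
                        cds=C.decode_cds(arr),
                        protein=C.translate(arr),
                        fpkm=fp,
                        category=cat,
                    )
                )
        self.leaf_genomes[species] = genes

    # ----- main recursion --------------------------------------------------

    def run(self) -> SimulationTruth:
        cfg = self.cfg
        root_ln = _Lineage()
        root_ln.m = self.e0.copy()
        if cfg.evolve_sequences:
            root_ln.seqs = {g.gene_id: C.encode_cds(g.cds) for g in self.ancestor}
            order: dict[str, list[str]] = {}
            for g in self.ancestor:
                order.setdefault(g.scaffold, []).append(g.gene_id)
            root_ln.order = order

        def walk(node, ln: _Lineage) -> None:
            if node.label == "wgd" and not ln.post_wgd:
                # the WGD shortly predates the first speciation: double the
                # genome, then evolve the shared post-WGD stem
                self._do_wgd(ln)
                if cfg.wgd_stem > 0:
                    self._branch(ln, cfg.wgd_stem, "wgd_stem")
            if node.is_leaf():
                self._emit_leaf(ln, node.taxon.label)
                return
            kids = node.child_nodes()
            for i, ch in enumerate(kids):
                child_ln = ln if i == len(kids) - 1 else ln.clone()
                self._branch(child_ln, ch.edge.length or 0.0, ch.label)
                walk(ch, child_ln)

        walk(self.tree.seed_node, root_ln)

        sp = sorted(self.leaf_states)
        state_map = {0: "BOTH", 1: "A", 2: "B"}
        df = pd.DataFrame(
            {s: [state_map[v] for v in self.leaf_states[s]] for s in sp},
            index=self.pair_ids,
        )
        return SimulationTruth(
            config=cfg,
            newick=self.tree.as_string(schema="newick").strip(),
            pair_ids=self.pair_ids,
            anchor={p: (p + "A", p + "B") for p in self.pair_ids},
            pair_scaffold=self.pair_scaffold,
            leaf_states=df,
            leaf_expression=self.leaf_expr,
            events=self.events,
            categories=self.categories,
        )


def simulate(cfg: SimConfig) -> tuple[dict[str, list[GeneModel]], dendropy.Tree, SimulationTruth]:
    """Run the full forward simulation.

    Returns ``(leaf genomes, species tree, truth)``. With
    ``cfg.evolve_sequences=False`` only presence/absence, copy identity and
    expression are simulated (genomes dict is empty) — the fast path for
    loss-dynamics studies at large gene counts.
    """
    sim = _Simulator(cfg)
    truth = sim.run()
    return sim.leaf_genomes, sim.tree, truth


def realized_pair_ks(
    truth: SimulationTruth,
    tree: dendropy.Tree,
    species: str,
    rng: np.random.Generator,
    syn_sites: float = 100.0,
) -> pd.Series:
    """Sampled ohnolog Ks per retained pair at one leaf, for loss-only runs.

    Divergence between retained copies is 2x the WGD-to-leaf path; a
    Poisson draw over a nominal number of synonymous sites adds the
    counting noise a sequence-based estimate would show. Conversion is not
    reflected here (use sequence mode for conversion studies).
    """
    dist = node_distance_from(tree, "wgd")[species]
    pairs = truth.leaf_states.index[truth.leaf_states[species] == "BOTH"]
    lam = 2.0 * dist * syn_sites
    vals = rng.poisson(lam, size=len(pairs)) / syn_sites
    return pd.Series(vals, index=pairs, name=species)


# ---------------------------------------------------------------------------
# presence matrix from truth


def presence_matrix_from_truth(
    truth: SimulationTruth,
    na_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(states, copies): states in {BOTH, ONE, NA}; copies give the
    surviving copy ('A'/'B') for ONE cells, else empty string. ``na_rate``
    masks cells at random to emulate missing data."""
    states = truth.leaf_states.copy()
    copies = states.where(states != "BOTH", "")
    states = states.replace({"A": ONE, "B": ONE})
    if na_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        mask = rng.random(states.shape) < na_rate
        states = states.mask(mask, "NA")
        copies = copies.mask(mask, "")
    return states, copies


# ---------------------------------------------------------------------------
# dataset I/O


def write_dataset(
    genomes: dict[str, list[GeneModel]],
    tree: dendropy.Tree,
    truth: SimulationTruth,
    outdir: str | Path,
) -> None:
    """Write per-species FASTA/TSV files, the species tree and truth JSON.

    Output is byte-deterministic for a fixed-seed simulation.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in sorted(genomes):
        genes = genomes[sp]
        with open(out / f"{sp}.prot.fa", "w") as fh:
            for g in genes:
                fh.write(f">{g.gene_id}\n{g.protein}\n")
        with open(out / f"{sp}.cds.fa", "w") as fh:
            for g in genes:
                fh.write(f">{g.gene_id}\n{g.cds}\n")
        with open(out / f"{sp}.positions.tsv", "w") as fh:
            fh.write("gene_id\tscaffold\trank\tstrand\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.scaffold}\t{g.rank}\t{g.strand}\n")
        with open(out / f"{sp}.expression.tsv", "w") as fh:
            fh.write("gene_id\tfpkm\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.fpkm:.6g}\n")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(truth.newick + "\n")
    payload = {
        "config": asdict(truth.config),
        "pair_ids": truth.pair_ids,
        "pair_scaffold": truth.pair_scaffold,
        "leaf_states": {sp: truth.leaf_states[sp].tolist() for sp in truth.leaf_states},
        "events": truth.events,
        "categories": truth.categories,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=0, sort_keys=True)
        fh.write("\n")


def read_dataset(outdir: str | Path) -> tuple[dict[str, list[GeneModel]], dendropy.Tree, dict]:
    """Round-trip reader for :func:`write_dataset` output."""
    out = Path(outdir)
    genomes: dict[str, list[GeneModel]] = {}
    for pos_file in sorted(out.glob("*.positions.tsv")):
        sp = pos_file.name.split(".")[0]
        pos = pd.read_csv(pos_file, sep="\t")
        expr = pd.read_csv(out / f"{sp}.expression.tsv", sep="\t").set_index("gene_id")
        prots = _read_fasta(out / f"{sp}.prot.fa")
        cds = _read_fasta(out / f"{sp}.cds.fa")
        genes = []
        for _, row in pos.iterrows():
            gid = row.gene_id
            genes.append(
                GeneModel(
                    gene_id=gid, species=sp, scaffold=row.scaffold, rank=int(row["rank"]),
                    strand=row.strand, cds=cds[gid], protein=prots[gid],
                    fpkm=float(expr.loc[gid, "fpkm"]),
                )
            )
        genomes[sp] = genes
    tree = dendropy.Tree.get(path=str(out / "tree.nwk"), schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return genomes, tree, truth


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
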