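"""Mapping ohnolog losses onto the species tree and loss-dynamics statistics.

Ancestral pair states are reconstructed by Dollo-style parsimony under a
zero-gain assumption with explicit missing-data (NA) rules:

* ancestor(BOTH, x) = BOTH for x in {BOTH, ONE, NA}
* ancestor(ONE, ONE) = ONE
* ancestor(ONE, NA) = NA
* ancestor(NA, NA) = NA

Loss events map to branches whose parent is BOTH and child is ONE. Node
survival is the fraction of root-present pairs still duplicated at the
node, plotted against the node's distance from the WGD (branch lengths in
Ks units, the divergence-as-time proxy), and fitted with one- and
two-phase exponential decay models compared by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import BOTH, ONE, NA

_CODE = {BOTH: 0, ONE: 1, NA: 2}
_STATE = {v: k for k, v in _CODE.items()}


def _find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node.label == label or (node.taxon is not None and node.taxon.label == label):
            return node
    raise KeyError(f"node {label!r} not in tree")


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


@dataclass
class AncestralStates:
    """Per-node reconstructed states and branch-mapped loss events."""

    states: pd.DataFrame  # nodes x pairs, values in {BOTH, ONE, NA}
    losses: pd.DataFrame  # columns: pair, branch (child node label)
    root_label: str

    def n_both(self, node_label: str) -> int:
        return int((self.states.loc[node_label] == BOTH).sum())


def ancestral_states(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    root_label: str = "wgd",
) -> AncestralStates:
    """Post-order application of the zero-gain rule table.

    ``matrix``: pairs x species with values in {BOTH, ONE, NA}; every leaf
    below ``root_label`` must be a column.
    """
    root = _find_node(tree, root_label)
    leaves = [_leaf_label(lf) for lf in root.leaf_iter()]
    missing = [l for l in leaves if l not in matrix.columns]
    if missing:
        raise ValueError(f"leaves missing from matrix: {missing}")

    codes: dict[str, np.ndarray] = {}
    losses: list[tuple[str, str]] = []
    pairs = matrix.index

    def post(node) -> np.ndarray:
        if node.is_leaf():
            arr = matrix[_leaf_label(node)].map(_CODE).to_numpy(dtype=np.int8)
            codes[_leaf_label(node)] = arr
            return arr
        kids = [post(ch) for ch in node.child_nodes()]
        st = kids[0]
        for other in kids[1:]:
            any_both = (st == 0) | (other == 0)
            both_one = (st == 1) & (other == 1)
            st = np.where(any_both, 0, np.where(both_one, 1, 2)).astype(np.int8)
        codes[node.label] = st
        return st

    post(root)

    def collect(node):
        for ch in node.child_nodes():
            lab = _leaf_label(ch) if ch.is_leaf() else ch.label
            parent_states = codes[node.label if not node.is_leaf() else _leaf_label(node)]
            child_states = codes[lab]
            for i in np.flatnonzero((parent_states == 0) & (child_states == 1)):
                losses.append((pairs[i], lab))
            if not ch.is_leaf():
                collect(ch)

    collect(root)
    states = pd.DataFrame(
        {lab: [ _STATE[v] for v in arr ] for lab, arr in codes.items()}, index=pairs
    ).T
    loss_df = pd.DataFrame(losses, columns=["pair", "branch"])
    return AncestralStates(states=states, losses=loss_df, root_label=root_label)


# ---------------------------------------------------------------------------
# survival decay


def survival_curve(
    anc: AncestralStates, tree: dendropy.Tree, root_label: str | None = None
) -> pd.DataFrame:
    """survival(node) = pairs BOTH at node / pairs BOTH at root, against
    the node's Ks distance from the root (WGD)."""
    root_label = root_label or anc.root_label
    root = _find_node(tree, root_label)
    n_root = anc.n_both(root_label)
    if n_root == 0:
        raise ValueError("no duplicated pairs at the root")
    dist = {root_label: 0.0}
    rows = [(root_label, 0.0, 1.0)]
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in node.child_nodes():
            lab = _leaf_label(ch) if ch.is_leaf() else ch.label
            parent_lab = node.label if node is not root else root_label
            dist[lab] = dist[parent_lab] + (ch.edge.length or 0.0)
            rows.append((lab, dist[lab], anc.n_both(lab) / n_root))
            stack.append(ch)
    return pd.DataFrame(rows, columns=["node", "distance", "survival"]).sort_values(
        ["distance", "node"], ignore_index=True
    )


@dataclass
class DecayFit:
    """One- vs two-phase exponential survival decay."""

    model: str  # preferred model: 'one_phase' | 'two_phase'
    rate: float  # one-phase lambda
    rates2: tuple[float, float]  # two-phase (lambda1, lambda2)
    mix: float  # two-phase mixing proportion p
    rss_one: float
    rss_two: float
    aicc_one: float
    aicc_two: float

    @property
    def delta_aicc(self) -> float:
        """aicc_one - aicc_two; > 2 supports the two-phase model."""
        return self.aicc_one - self.aicc_two


def _aicc(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        rss = 1e-300
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def fit_decay(
    points: pd.DataFrame,
    aicc_margin: float = 2.0,
    min_phase: float = 0.15,
    min_rate_ratio: float = 2.0,
) -> DecayFit:
    """Least-squares fits of S = exp(-l d) and the two-phase mixture.

    The two-phase model is preferred only when (i) its AICc beats the
    one-phase AICc by more than ``aicc_margin`` and (ii) the fitted
    mixture is identifiable as two phases: both components carry at least
    ``min_phase`` of the pairs and the rates differ by at least
    ``min_rate_ratio``-fold. Degenerate mixtures (a vanishing fast
    component absorbing reconstruction wobble near the origin) are not
    evidence for a second phase.
    """
    d = points["distance"].to_numpy(float)
    s = points["survival"].to_numpy(float)
    if len(d) < 3:
        raise ValueError("need >= 3 survival points")

    pos = (s > 0) & (d > 0)
    lam0 = float(-np.polyfit(d[pos], np.log(s[pos]), 1)[0]) if pos.sum() >= 2 else 1.0
    lam0 = max(lam0, 1e-6)

    (lam,), _ = optimize.curve_fit(
        lambda x, l: np.exp(-l * x), d, s, p0=[lam0], bounds=(1e-12, np.inf), maxfev=10000
    )
    rss1 = float(np.sum((s - np.exp(-lam * d)) ** 2))

    def two(x, p, l1, l2):
        return p * np.exp(-l1 * x) + (1 - p) * np.exp(-l2 * x)

    best = None
    for p0 in (0.3, 0.5, 0.7):
        for f1, f2 in ((4.0, 0.25), (2.0, 0.5), (8.0, 0.1)):
            try:
                popt, _ = optimize.curve_fit(
                    two, d, s, p0=[p0, lam * f1, lam * f2],
                    bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]), maxfev=20000,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((s - two(d, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
    if best is None:
        rss2, (p, l1, l2) = rss1, (1.0, lam, lam)
    else:
        rss2, (p, l1, l2) = best

    n = len(d)
    a1 = _aicc(rss1, n, k=2)
    a2 = _aicc(rss2, n, k=4)
    if l1 < l2:  # canonical order: fast phase first
        l1, l2, p = l2, l1, 1 - p
    identifiable = min(p, 1 - p) >= min_phase and l1 >= min_rate_ratio * max(l2, 1e-12)
    model = "two_phase" if (a1 - a2) > aicc_margin and identifiable else "one_phase"
    return DecayFit(
        model=model, rate=float(lam), rates2=(float(l1), float(l2)), mix=float(p),
        rss_one=rss1, rss_two=rss2, aicc_one=a1, aicc_two=a2,
    )


# ---------------------------------------------------------------------------
# retention vs divergence (with phylogenetically independent contrasts)


def pic_contrasts(tree: dendropy.Tree, values: dict[str, float], root_label: str = "wgd",
                  eps: float = 1e-9) -> np.ndarray:
    """Standardized independent contrasts of a trait on a rooted binary tree."""
    root = _find_node(tree, root_label)
    contrasts: list[float] = []

    def post(node) -> tuple[float, float]:
        if node.is_leaf():
            return values[_leaf_label(node)], (node.edge.length or 0.0) + eps
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("PIC requires a binary tree")
        (x1, v1), (x2, v2) = post(kids[0]), post(kids[1])
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        xk = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        vk = (node.edge.length or 0.0) + eps + v1 * v2 / (v1 + v2)
        return xk, vk

    post(root)
    return np.array(contrasts)


@dataclass
class CorrelationReport:
    r: float
    p: float
    pic_r: float
    pic_p: float
    n: int


def retention_vs_divergence(
    retention: pd.Series, mean_ks: pd.Series, tree: dendropy.Tree, root_label: str = "wgd"
) -> CorrelationReport:
    """Pearson and PIC correlation between per-species retention fraction
    and per-species mean ohnolog Ks."""
    species = sorted(set(retention.index) & set(mean_ks.index))
    if len(species) < 4:
        raise ValueError("need >= 4 species")
    x = retention.loc[species].astype(float)
    y = mean_ks.loc[species].astype(float)
    r, p = stats.pearsonr(x, y)
    u = pic_contrasts(tree, dict(x), root_label)
    v = pic_contrasts(tree, dict(y), root_label)
    pic_r = float(np.sum(u * v) / math.sqrt(np.sum(u * u) * np.sum(v * v)))
    df = len(u) - 1
    if abs(pic_r) >= 1.0:
        pic_p = 0.0
    else:
        t = pic_r * math.sqrt(df / (1 - pic_r**2))
        pic_p = 2 * stats.t.sf(abs(t), df)
    return CorrelationReport(float(r), float(p), pic_r, float(pic_p), len(species))


# ---------------------------------------------------------------------------
# parallel vs reciprocal loss


def classify_loss_pattern(
    mrca_state: str, surviving_x: str | None, surviving_y: str | None
) -> str:
    """'parallel' | 'reciprocal' | 'none' for one pair and two species.

    ``mrca_state`` is the reconstructed state at the species' MRCA;
    anything but BOTH means the losses were not independent. Surviving
    copies are 'A'/'B' (None/empty if the species still has both or data
    are missing)."""
    if mrca_state != BOTH or not surviving_x or not surviving_y:
        return "none"
    return "parallel" if surviving_x == surviving_y else "reciprocal"


def count_loss_patterns(
    tree: dendropy.Tree,
    matrix: pd.DataFrame,
    copies: pd.DataFrame,
    root_label: str = "wgd",
    independence: str = "mrca",
) -> pd.DataFrame:
    """Parallel/reciprocal loss counts for every species pair.

    ``copies`` gives the surviving copy for ONE cells ('' otherwise).
    ``distance`` is the Ks path from the WGD to the pair's MRCA (the
    divergence between duplication and speciation).

    ``independence`` selects which double losses count as independent:
    ``"mrca"`` (the reconstructed MRCA state is BOTH — the conventional
    rule) or ``"terminal"`` (both losses map to the species' own terminal
    branches; such events are private to one species, so counts over
    species pairs sharing no species are statistically independent —
    use for calibrated null tests).
    """
    if independence not in ("mrca", "terminal"):
        raise ValueError("independence must be 'mrca' or 'terminal'")
    anc = ancestral_states(tree, matrix, root_label)
    terminal_loss: dict[str, np.ndarray] = {}
    if independence == "terminal":
        pair_index = {p: i for i, p in enumerate(matrix.index)}
        for leaf in matrix.columns:
            arr = np.zeros(len(matrix), dtype=bool)
            sub = anc.losses[anc.losses.branch == leaf]
            for p in sub["pair"]:
                arr[pair_index[p]] = True
            terminal_loss[leaf] = arr
    root = _find_node(tree, root_label)
    leaves = [_leaf_label(lf) for lf in root.leaf_iter()]
    dist = {root_label: 0.0}
    mrca_label: dict[tuple[str, str], str] = {}

    def walk(node, d, below):
        lab = node.label if not node.is_leaf() else _leaf_label(node)
        dist[lab] = d
        groups = []
        for ch in node.child_nodes():
            sub = walk(ch, d + (ch.edge.length or 0.0), below)
            groups.append(sub)
        if node.is_leaf():
            return [lab]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        key = (a, b) if a < b else (b, a)
                        mrca_label[key] = lab
        return [x for g in groups for x in g]

    walk(root, 0.0, None)

    rows = []
    state_arr = {l: matrix[l].to_numpy() for l in leaves}
    copy_arr = {l: copies[l].fillna("").to_numpy() for l in leaves}
    for i, x in enumerate(sorted(leaves)):
        for y in sorted(leaves)[i + 1 :]:
            m = mrca_label[(x, y)]
            cx, cy = copy_arr[x], copy_arr[y]
            independent = (
                (state_arr[x] == ONE) & (state_arr[y] == ONE)
                & (cx != "") & (cy != "")
            )
            if independence == "terminal":
                independent &= terminal_loss[x] & terminal_loss[y]
            else:
                independent &= (anc.states.loc[m] == BOTH).to_numpy()
            n_par = int(np.sum(independent & (cx == cy)))
            n_rec = int(np.sum(independent & (cx != cy)))
            rows.append((x, y, n_par, n_rec, dist[m]))
    return pd.DataFrame(
        rows, columns=["species_x", "species_y", "n_parallel", "n_reciprocal", "distance"]
    )


def parallel_trend(counts: pd.DataFrame, min_events: int = 1) -> tuple[float, float]:
    """Pearson correlation of the parallel-loss fraction with the
    WGD-to-speciation distance; (nan, nan) when degenerate."""
    sub = counts[(counts.n_parallel + counts.n_reciprocal) >= min_events]
    if len(sub) < 3:
        return float("nan"), float("nan")
    frac = sub.n_parallel / (sub.n_parallel + sub.n_reciprocal)
    if frac.nunique() <= 1 or sub.distance.nunique() <= 1:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(sub.distance, frac)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# expression-biased loss


def proportion_test_half(x: int, n: int, p0: float = 0.5) -> float:
    """One-sample proportion test against p0 with continuity correction
    (chi-square with Yates correction), two-sided p-value."""
    if n == 0:
        return float("nan")
    num = max(abs(x - n * p0) - 0.5, 0.0)
    chi2 = num**2 / (n * p0 * (1 - p0))
    return float(stats.chi2.sf(chi2, 1))


@dataclass
class BiasedLossReport:
    """Expression-divergence and low-expression bias of ortholog loss."""

    loss_rate_top: float  # loss rate among most expression-divergent pairs
    loss_rate_rest: float
    chi2_p: float
    frac_low_expressed_lost: float  # of losses, fraction hitting the ortholog
    n_losses: int  # of the lower-expressed copy
    prop_p: float


def expression_biased_loss(
    table: pd.DataFrame, top_quantile: float = 0.05
) -> BiasedLossReport:
    """Bias statistics for ohnolog pairs retained in species A vs their
    ortholog fate in species B.

    ``table`` columns: ``expr_a``/``expr_b`` (log expression of copies A/B
    in the species retaining both) and ``state_b`` ('BOTH', or the copy
    surviving in the other species: 'A'/'B').
    """
    tab = table.dropna(subset=["expr_a", "expr_b", "state_b"])
    div = (tab.expr_a - tab.expr_b).abs()
    thresh = div.quantile(1 - top_quantile)
    top = div >= thresh
    lost = tab.state_b != BOTH
    k = int(lost[top].sum())
    cont = np.array(
        [[k, int(top.sum()) - k], [int(lost[~top].sum()), int((~top).sum() - lost[~top].sum())]]
    )
    try:
        _, chi2_p, _, _ = stats.chi2_contingency(cont, correction=True)
    except ValueError:  # degenerate table (all lost or all retained)
        chi2_p = float("nan")

    lost_tab = tab[lost]
    low_copy = np.where(lost_tab.expr_a < lost_tab.expr_b, "A", "B")
    lost_copy = np.where(lost_tab.state_b == "B", "A", "B")
    hits = int((low_copy == lost_copy).sum())
    n = len(lost_tab)
    return BiasedLossReport(
        loss_rate_top=float(lost[top].mean()) if top.any() else float("nan"),
        loss_rate_rest=float(lost[~top].mean()) if (~top).any() else float("nan"),
        chi2_p=float(chi2_p),
        frac_low_expressed_lost=hits / n if n else float("nan"),
        n_losses=n,
        prop_p=proportion_test_half(hits, n),
    )
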