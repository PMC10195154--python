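"""Core data containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """One protein-coding gene.

    ``rank`` is the 0-based position of the gene on its scaffold; synteny
    operations use rank order only (strand is carried but ignored).
    """

    gene_id: str
    species: str
    scaffold: str
    rank: int
    strand: str = "+"
    cds: str = ""
    protein: str = ""
    fpkm: float = 0.0
    category: str | None = None


@dataclass(frozen=True)
class HitScore:
    """Similarity between two proteins (global alignment score)."""

    query_id: str
    subject_id: str
    score: float
    identity: float


@dataclass(frozen=True)
class DivergenceEstimate:
    """Synonymous / nonsynonymous divergence for one gene pair.

    ``ka_ks`` is ``None`` when Ks is zero; ``saturated`` flags pairs where
    the Jukes-Cantor correction is undefined (p >= 3/4 on either class of
    sites), in which case the corresponding rate is reported as ``inf``.
    """

    ks: float
    ka: float
    ka_ks: float | None
    saturated: bool = False


@dataclass(frozen=True)
class AnchorPair:
    """Within-genome WGD anchor: a reciprocal-best-hit paralog pair.

    ``gene1_id < gene2_id`` canonically.
    """

    gene1_id: str
    gene2_id: str
    divergence: DivergenceEstimate | None = None

    def __post_init__(self):
        if self.gene1_id >= self.gene2_id:
            raise ValueError("anchor genes must be in canonical (sorted) order")


@dataclass
class ParalogousBlock:
    """A colinear run of WGD anchors between two scaffold segments."""

    scaffold1: str
    scaffold2: str
    span1: tuple[int, int]  # inclusive rank range on scaffold1
    span2: tuple[int, int]
    anchors: list[AnchorPair] = field(default_factory=list)
    syntenic_additions: list[tuple[str, str]] = field(default_factory=list)
    orientation: int = 1  # +1 co-oriented, -1 flipped


RETAINED_BOTH = "RETAINED_BOTH"
SINGLE_COPY = "SINGLE_COPY"


@dataclass
class PairStatus:
    """Retention status of one ancestral locus inside a paralogon."""

    locus_id: str
    status: str  # RETAINED_BOTH or SINGLE_COPY
    gene1_id: str | None = None  # copy on scaffold1 (None if lost)
    gene2_id: str | None = None  # copy on scaffold2

    def surviving(self) -> list[str]:
        return [g for g in (self.gene1_id, self.gene2_id) if g is not None]


@dataclass
class Paralogon:
    """Fused paralogous blocks sharing one scaffold pair."""

    paralogon_id: str
    scaffold1: str
    scaffold2: str
    blocks: list[ParalogousBlock] = field(default_factory=list)
    statuses: list[PairStatus] = field(default_factory=list)

    @property
    def span1(self) -> tuple[int, int]:
        return (min(b.span1[0] for b in self.blocks), max(b.span1[1] for b in self.blocks))

    @property
    def span2(self) -> tuple[int, int]:
        return (min(b.span2[0] for b in self.blocks), max(b.span2[1] for b in self.blocks))

    @property
    def n_anchors(self) -> int:
        return sum(len(b.anchors) for b in self.blocks)


@dataclass
class AncestralLocus:
    """One locus of the reconstructed pre-WGD ancestor."""

    locus_id: str
    representative: str
    order: int


# Presence-matrix cell states (loss mapping)
BOTH = "BOTH"
ONE = "ONE"
NA = "NA"
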