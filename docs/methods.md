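# Methods

`ohnolog` analyses the fate of gene duplicates created by a whole-genome
duplication (WGD) across a clade of descendant genomes, and ships a
forward simulator that generates fully ground-truthed inputs for every
stage. This note records the models, the parameters that matter, the
numerical choices, and what the simulation-based tests do and do not show.

## The forward simulator

### Model

A pre-WGD ancestor of `n_genes` protein-coding genes on `n_scaffolds`
scaffolds is generated with random stop-free CDS (`min_codons`–`max_codons`
codons, default 150–450, ordinary gene sizes), lognormal FPKM
(`ln FPKM ~ N(2, 1.5)`, a heavy-tailed expression distribution) and flat
functional-category labels. A single WGD copies every gene onto a mirrored
scaffold, preserving gene order. The ingroup radiates from a most recent
common ancestor that postdates the WGD by `wgd_stem` (default 0.1) — the
duplication shortly precedes the first speciation, which is what makes the
two copies distinguishable at all. Outgroup lineages attach below the WGD
and stay single-copy.

All branch lengths are in expected synonymous substitutions per site per
lineage ("Ks units"), so divergence and time share one scale. The ingroup
tree is ultrametric with split times `depth * Beta(1, radiation_shape)`;
the default shape 1.5 spreads speciations over the whole post-WGD period
(the clade contains both deep splits and recent sister species — a fully
compressed radiation would make several downstream statistics
uninformative). `rate_variation` (lognormal per-branch rate multipliers,
default 0) adds lineage rate heterogeneity; with hazards defined per Ks
unit, it is the mechanism that couples per-species divergence to
per-species retention.

Along every branch of length `t`:

* **Copy loss.** Each still-duplicated pair loses one copy with
  probability `1 - exp(-h t)`, where
  `h = base_loss_rate * exp(-expression_beta * centred log10 FPKM) * category_effect`.
  Loss is instantaneous deletion — no pseudogene intermediate — because
  the analysis scores presence/absence of intact genes. The lost copy is
  `A` with probability `1 / (1 + exp(asymmetry_strength * d))`, where `d`
  is the copies' log10-expression difference. `d` performs a Brownian walk
  at rate `predetermination_drift` per √Ks: the lower-expressed copy
  carries the larger hazard share, and the bias hardens over time. This
  single mechanism produces both the parallel-loss excess between
  late-diverging species and the loss bias toward the ortholog of the
  lower-expressed copy. Note that divergence in `d` redistributes hazard
  between the copies without changing the pair's total loss hazard; the
  pipeline's χ²-test comparing loss rates of expression-divergent vs other
  pairs is therefore ~null under simulation, although the statistic itself
  is implemented and reported.
* **Substitutions.** Synonymous and nonsynonymous changes accrue as
  Poisson processes with rates proportional to Nei–Gojobori site counts
  and `Ka/Ks = omega` (default 0.05, strong purifying selection typical of
  retained ohnologs). A codon-position scheme (synonymous alternatives
  enumerated per codon, stop codons never created) replaces a full codon
  model: only counting-level Ks/Ka recovery is needed. No indels are
  simulated.
* **Gene conversion.** Tracts initiate per ancestral scaffold at
  `conversion_rate` per Ks, span `1 + Geometric(1/conversion_tract_len)`
  loci, and overwrite one copy with the other for every still-duplicated
  locus in the tract, resetting divergence at the conversion time.
* **Single-gene duplication (SGD).** Rate `sgd_rate` per gene per Ks
  (default 5e-4, matching the observed extreme paucity of recent SGDs —
  a few tens per tens-of-thousands-of-genes genome); the copy is inserted
  next to its source and diverges from the event time onward.
* **Translocation.** `translocation_rate` per gene per Ks (default 0.01)
  moves a gene to a uniformly random position.
* **Expression drift.** The pair-mean log10 expression walks at
  `expression_drift` per √Ks.

Defaults (`depth=0.5`, `wgd_stem=0.1`, `base_loss_rate=1.1`) give ohnolog
Ks near 1.2 and median leaf retention near 0.52 — the regime of a recent
ciliate-style WGD. `evolve_sequences=False` skips sequences, conversions,
SGDs and translocations, simulating only presence/absence, copy identity
and expression; this fast path powers the loss-dynamics statistics at
thousands of pairs, with `realized_pair_ks` supplying Poisson-sampled Ks
values in place of sequence-based estimates (conversion is not reflected
in that shortcut).

### What the generator does not emulate

Assembly fragmentation (scaffolds are chromosome-scale), annotation error,
missing data (NA cells must be injected explicitly), indels, rearrangement
beyond single-gene translocation, pseudogenes, and the older duplication
rounds real post-WGD genomes carry. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
performance on real assemblies.

## Homology

Similarity search is exact global alignment (BLOSUM62, gap open −11,
extend −1) behind a shared-5-mer prefilter; pairs with non-positive score
are discarded as unrelated. Reciprocal best hits (RBH) break ties
lexicographically (logged) for determinism. Families are connected
components of the cross-species RBH graph augmented with within-genome
ohnolog RBH edges.

Ks/Ka uses Nei–Gojobori counting: sites averaged between sequences,
multi-base codon differences averaged over substitution orderings
(skipping paths through stops), Jukes–Cantor correction with a `saturated`
flag when `p >= 3/4`. Unequal-length CDS are aligned through their
proteins and gapped codons dropped. Gene trees are neighbor joining;
`build_gene_tree` accepts a precomputed distance matrix, and the pipeline
feeds CDS p-distances (see below).

## Paralogons

Within-genome RBH anchors are chained per scaffold pair (colinear,
consecutive anchors ≤ `max_gap` ranks apart on both scaffolds, one
orientation per block, ≥ `min_anchors` per block; the classic scanning
window is subsumed by the gap tolerance), blocks are extended with non-RBH
syntenic family matches inside their spans, and co-oriented adjacent
blocks fuse into paralogons (`fuse_gap`). Status calling assigns every
retained-pair candidate to one locus — preferring the paralogon containing
both genes on opposite scaffolds, falling back to a single-side match for
relocated partners — and every other gene inside an (extended) span to a
single-copy locus; genes outside any span stay unassigned rather than
being scored as losses. Same-scaffold pairs within 5 ranks are treated as
tandem duplicates, never ohnolog loci. Ancestral reconstruction picks one
representative per locus (seeded random choice for retained pairs) in
block order; iterating on the reconstructed genome would peel older
duplication rounds. Defaults (`min_anchors=3`, `max_gap=5`, `fuse_gap=10`,
`span_extend=10`) recover ≥ 95% correct paralogon assignment and the exact
ancestral gene count on default simulations; they are configuration
values, not biological claims.

## Orthology

Close to a WGD the two copies are nearly identical in protein sequence
(Ka/Ks ≈ 0.05), so copy discrimination runs on **CDS p-distance** — the
silent sites carry the signal. Within-family mutual-closest pairs are
annotated 1-to-1 / 1-to-2 / 2-to-2. 1-to-1 calls are *forced* pairings
(one gene per side regardless of copy) and carry no copy information;
only the copy-informative kinds feed the scaffold "orthology score"
(count of candidate pairs linking two scaffolds). Resolution of 1-to-2
relations compares the two candidate scaffold pairs, preferring the
**aggregate-divergence channel** (mean within-family CDS distance of all
gene links between the scaffolds, lower wins) with the count score as
fallback: averaging the tiny per-gene signal over a whole scaffold makes
the copy assignment decisive even for species that split immediately
after the WGD. Ties stay unresolved (logged).

Gene trees are midpoint-rooted (for a WGD family the deepest split is the
copy split; families lacking one side fall back to midpoint anyway, which
is why that is the default). Ortholog groups grow from sister pairs of
different species; walking rootward, unclaimed leaves are absorbed when
they add a new species, leaves duplicating a represented species are
skipped, and each gene joins at most one group (seeds processed in
lexicographic order). The paralogon graph weights an edge between two
paralogons by the number of gene trees whose groups link them; chains are
extracted greedily from the heaviest edge, extending both ends along the
heaviest compatible edges, each paralogon used once — a disjoint-path
interpretation of "most supported orthologous relations".

## Loss dynamics

Ancestral states follow zero-gain (Dollo-style) parsimony with explicit
missing-data rules: `(BOTH, x) → BOTH` for any x, `(ONE, ONE) → ONE`,
`(ONE, NA) → NA`, `(NA, NA) → NA`. Losses map to branches with parent
BOTH and child ONE; on complete data this equals exhaustive minimum-loss
enumeration (tested). Survival at a node is the fraction of root-present
pairs still duplicated, plotted against Ks distance from the root.

The decay is fitted by least squares with `S = exp(-λd)` and the two-phase
mixture `p·exp(-λ1 d) + (1-p)·exp(-λ2 d)`, compared by AICc with a Δ > 2
threshold **and an identifiability guard**: a mixture is only accepted as
two-phase when both components hold ≥ 15% of pairs and the rates differ
≥ 2-fold. Parsimony reconstruction slightly underestimates survival at
nodes with few descendant leaves, and an unconstrained mixture absorbs
that wobble with a vanishing fast component; a component carrying almost
no mass is not evidence for a second phase.

Retention-vs-divergence reports ordinary Pearson correlation and
Felsenstein's independent contrasts on the Ks-length tree (correlation
through the origin, t-test with df = contrasts − 1; zero-length branches
padded by 1e-9).

Parallel losses (two species independently losing the same copy) versus
reciprocal losses are counted per species pair. Two rules decide
independence: the conventional one (the pair's reconstructed MRCA state is
BOTH — note this structurally excludes sister-species double losses,
which parsimony folds into one ancestral event), and a `terminal` mode
requiring both losses on the species' own terminal branches. The terminal
mode exists for statistical calibration: internal-branch losses are shared
between many species-pair cells, so nominal p-values on all 78 cells are
strongly anticonservative (~40% null rejections measured); terminal losses
are private to one species, making counts over disjoint species pairs
exactly binomial. The headline trend statistic (parallel fraction vs
WGD-to-speciation distance, all pairs) is reported in the conventional
form; null calibration checks use the terminal/disjoint form.

The expression-biased-loss report takes pairs retained in species A with
their copy expressions and the ortholog fate in species B, and returns
(i) the loss rate among the top-5% expression-divergent pairs vs the rest
(χ² with Yates correction) and (ii) the fraction of losses hitting the
ortholog of A's lower-expressed copy, tested against 0.5 by a one-sample
proportion test with continuity correction (matching R's `prop.test`).

## Retention analysis

Expression level is `log10(FPKM + 0.1)` (base 10 by convention; the offset
keeps zero-FPKM genes finite). The cross-species retention rate of an
ancestral gene is (#species with BOTH)/(#species with ≥ 1 ortholog);
genes with no ingroup ortholog are excluded, not scored 0. Binned
retention uses 14 equal-count expression bins with a normal-approximation
95% CI (mean ± 1.96 SE). Category bias averages retention per category at
the gene level, correlates the per-category means between two clades, and
screens enrichment by permuting retention values within expression strata
(5 quantile strata, 2000 permutations, add-one two-sided p, BH FDR) — an
assumption-free way of asking whether a category is over/under-retained
beyond what its expression predicts.

## Conversion and single-gene duplications

The Ks series of each paralogon (retained loci in ancestral order, blocks
concatenated) is segmented by penalized binary segmentation on a Gaussian
mean cost. Noise is estimated from the median absolute first difference
(robust to the very level shifts being sought) and the penalty is
`5 σ² log n` — larger than a textbook BIC constant because binary
segmentation scans the maximum over all split points; the factor holds the
per-profile false-positive rate at or below ~5% for profile lengths 15–60.
Minimum segment 3 loci; profiles shorter than 10 loci are skipped
(logged). Downward segments are flagged as candidate conversions only if
a one-sided Mann–Whitney test against the rest of the profile rejects at
α = 0.05; upward shifts are reported but never called conversions. The
per-genome summary is flagged/testable paralogons.

SGD calling applies ordered filters with logged removal counts:
within-genome RBH; not an annotated ohnolog pair; **both** genes inside
some paralogon span (the stricter reading — guards against relocated
ohnologs); Ks < 1 (recent). A per-species exclusion is a caller concern
(species with compromised assemblies can simply be left out of the loop).

## WGD placement

For a fixed ladder quartet (((T1,T2),T3),OUT) each gene tree is pruned to
copies of the four taxa (discarded unless all four are present), rooted on
the lexicographically first OUT copy, and scanned root-down for the first
node whose children's species sets overlap — a species-overlap duplication
node. Its subtended species set maps to the ladder branch above that set's
MRCA; trees without a duplication vote "unassigned". Percentages over all
subtrees are banded ≥50% / ≥25% / <25%. This distils a multi-taxon
paleopolyploidy search to the quartet case; significance testing against
null simulations of the full method is out of scope.

## Problem sizes and determinism

Simulation-backed tests use 1.5–5k pairs (loss-only) and 120–500 genes
(sequence-level) over 2–13 species — sizes where every closed-form and
truth-recovery check is sharp while the whole suite runs in minutes on one
CPU. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; every stage, including dataset files on disk, is
byte-identical across runs with the same seed. Tie-breaks are
lexicographic throughout and logged where they matter.
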