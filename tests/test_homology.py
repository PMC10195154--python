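"""Similarity search, RBH, families, Ks/Ka and gene trees."""

import random

import dendropy
import numpy as np
import pytest

from ohnolog import codons as C
from ohnolog.homology import (
    GAP_EXTEND,
    GAP_OPEN,
    build_gene_tree,
    cluster_families,
    estimate_ks_ka,
    reciprocal_best_hits,
    score_pair,
    within_genome_rbh,
)
from ohnolog.models import GeneModel
from ohnolog.simulate import SimConfig, apply_wgd, generate_ancestral_genome, simulate

AAS = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_score(a: str, b: str) -> float:
    """Textbook O(nm) global affine-gap alignment score (independent
    oracle for the aligner behind score_pair)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND,
                          Y[i - 1][j] + GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND,
                          X[i][j - 1] + GAP_OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


class TestScorePair:
    def test_identical_sequences(self):
        hit = score_pair("MKLVAN", "MKLVAN")
        assert hit.identity == 1.0

    def test_symmetry(self):
        rng = random.Random(1)
        for _ in range(5):
            a = "".join(rng.choice(AAS) for _ in range(40))
            b = "".join(rng.choice(AAS) for _ in range(35))
            assert score_pair(a, b).score == score_pair(b, a).score

    def test_matches_gotoh_oracle(self):
        rng = random.Random(7)
        for _ in range(20):
            la, lb = rng.randint(5, 30), rng.randint(5, 30)
            a = "".join(rng.choice(AAS) for _ in range(la))
            b = "".join(rng.choice(AAS) for _ in range(lb))
            assert score_pair(a, b).score == pytest.approx(gotoh_score(a, b))

    def test_rejects_bad_characters(self):
        with pytest.raises(ValueError):
            score_pair("MKL*", "MKL")
        with pytest.raises(ValueError):
            score_pair("", "MKL")


def _gene(gid, species, scaffold, rank, protein, cds=""):
    return GeneModel(gid, species, scaffold, rank, "+", cds, protein)


class TestRBH:
    def test_identical_single_gene_sets(self):
        a = [_gene("a1", "A", "s1", 0, "MKLVANDERQW" * 3)]
        b = [_gene("b1", "B", "s1", 0, "MKLVANDERQW" * 3)]
        assert reciprocal_best_hits(a, b) == [("a1", "b1")]

    def test_asymmetric_best_yields_no_pair(self):
        base = "MKLVANDERQWHHFG" * 3
        mutated = base[:10] + "A" + base[11:]
        a = [_gene("a1", "A", "s1", 0, mutated)]
        b = [_gene("b1", "B", "s1", 0, base), _gene("b2", "B", "s1", 1, mutated)]
        pairs = reciprocal_best_hits(a, b)
        # a1's unique best is the identical b2; b1 is nobody's best partner
        assert pairs == [("a1", "b2")]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_best_hits([], [_gene("b", "B", "s", 0, "MKL")])

    def test_within_genome_excludes_self(self):
        genome = generate_ancestral_genome(SimConfig(n_genes=30, n_scaffolds=2, seed=8))
        assert within_genome_rbh(genome) == []  # unrelated random genes


class TestFamilies:
    def test_disjoint_pairs_one_family_each(self):
        fams = cluster_families([("a", "b"), ("c", "d")])
        assert sorted(map(sorted, fams.values())) == [["a", "b"], ["c", "d"]]

    def test_permutation_invariant(self):
        e1 = [("a", "b"), ("b", "c"), ("d", "e")]
        assert cluster_families(e1) == cluster_families(list(reversed(e1)))

    def test_doubled_genome_family_count_equals_ancestral(self):
        genome = generate_ancestral_genome(SimConfig(n_genes=40, n_scaffolds=2, seed=3))
        doubled, _ = apply_wgd(genome)
        rbh = within_genome_rbh(doubled)
        fams = cluster_families(rbh)
        assert len(fams) == 40


class TestKsKa:
    def test_identical(self):
        cds = "ATGGCTTTACGAGAT"
        est = estimate_ks_ka(cds, cds)
        assert est.ks == 0.0 and est.ka == 0.0 and est.ka_ks is None

    def test_one_synonymous_change_matches_enumeration_oracle(self):
        """One third-position synonymous change in 10 codons: Ka = 0 and
        Ks = JC(1/S) with S counted per Nei-Gojobori."""
        codons = ["ATG", "GCT", "TTA", "CGA", "GAT", "AAA", "GGG", "CCC", "TTT", "CAT"]
        a = "".join(codons)
        b = "".join(["ATG", "GCC"] + codons[2:])  # GCT -> GCC (Ala, synonymous)
        # independent site count
        S = sum(brute_sites(c) for c in codons) / 2 + sum(
            brute_sites(c) for c in ["ATG", "GCC"] + codons[2:]
        ) / 2
        p = 1.0 / S
        expected_ks = -0.75 * np.log(1 - 4 * p / 3)
        est = estimate_ks_ka(a, b)
        assert est.ka == 0.0
        assert est.ks == pytest.approx(expected_ks, rel=1e-9)
        assert not est.saturated

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        non_stop = np.array(C.NON_STOP)
        for _ in range(5):
            x = C.decode_cds(non_stop[rng.integers(len(non_stop), size=20)])
            y = C.decode_cds(non_stop[rng.integers(len(non_stop), size=20)])
            ex, ey = estimate_ks_ka(x, y), estimate_ks_ka(y, x)
            assert ex.ks == pytest.approx(ey.ks) and ex.ka == pytest.approx(ey.ka)

    def test_length_error(self):
        with pytest.raises(ValueError):
            estimate_ks_ka("ATGG", "ATG")

    def test_recovers_simulated_divergence(self):
        """Ohnolog pairs simulated at Ks = 0.3: mean estimate within 10%."""
        cfg = SimConfig(
            n_genes=100, n_scaffolds=2, n_ingroup=2, n_outgroup=0,
            depth=0.15, wgd_stem=0.0, base_loss_rate=0.0, conversion_rate=0.0,
            sgd_rate=0.0, translocation_rate=0.0, seed=17,
        )
        genomes, _, truth = simulate(cfg)
        sp = truth.species[0]
        gmap = {g.gene_id: g for g in genomes[sp]}
        ks = [
            estimate_ks_ka(gmap[f"{sp}_{p}A"].cds, gmap[f"{sp}_{p}B"].cds).ks
            for p in truth.pair_ids
        ]
        assert np.mean(ks) == pytest.approx(0.3, rel=0.10)


def brute_sites(codon: str) -> float:
    syn = 0
    for pos in range(3):
        for base in "TCAG":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if C.AA[alt] == C.AA[codon]:
                syn += 1
    return syn / 3.0


class TestGeneTree:
    def test_three_leaves_trivial_topology(self):
        nwk = build_gene_tree({"a": "MKLV", "b": "MKLV", "c": "MRLV"})
        tree = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"a", "b", "c"}

    def test_nj_recovers_additive_topology(self):
        """Distances generated on a known 5-leaf tree are additive, so NJ
        must recover that topology exactly."""
        ref = dendropy.Tree.get(
            data="((a:1,b:2):1,(c:1.5,d:1):2,e:4);", schema="newick",
            preserve_underscores=True,
        )
        pdm = ref.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in ref.taxon_namespace}
        ids = sorted(taxa)
        dist = np.array(
            [[pdm.distance(taxa[i], taxa[j]) for j in ids] for i in ids]
        )
        nwk = build_gene_tree({i: "" for i in ids}, distances=dist)
        got = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=ref.taxon_namespace,
            preserve_underscores=True,
        )
        ref.encode_bipartitions()
        got.encode_bipartitions()
        ref_splits = {b.split_bitmask for b in ref.bipartition_encoding}
        got_splits = {b.split_bitmask for b in got.bipartition_encoding}
        assert ref_splits == got_splits

    def test_small_families(self):
        assert build_gene_tree({"x": "MK"}).startswith("(")
        assert "x" in build_gene_tree({"x": "MK", "y": "MR"})
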