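"""Conversion changepoints and single-gene duplication calling."""

import numpy as np
import pytest

from ohnolog.conversion_sgd import (
    best_single_split,
    converted_paralogon_summary,
    detect_changepoints,
    find_single_gene_duplications,
    flag_converted_segments,
    ks_profile,
    KsProfile,
)
from ohnolog.homology import within_genome_rbh
from ohnolog.models import GeneModel, PairStatus, Paralogon, ParalogousBlock
from ohnolog.paralogon import detect_paralogons
from ohnolog.simulate import SimConfig, apply_wgd, generate_ancestral_genome
from ohnolog import codons as C


def exhaustive_split_oracle(x, min_size=3):
    """Independent best mean-shift split by direct likelihood scan."""
    best_k, best_red = None, 0.0
    n = len(x)
    total = np.sum((x - x.mean()) ** 2)
    for k in range(min_size, n - min_size + 1):
        left, right = x[:k], x[k:]
        red = total - np.sum((left - left.mean()) ** 2) - np.sum((right - right.mean()) ** 2)
        if red > best_red:
            best_k, best_red = k, red
    return best_k, best_red


class TestChangepoints:
    def test_constant_series_no_changepoints(self):
        assert detect_changepoints(np.full(30, 0.8)) == []

    def test_two_level_series_matches_oracle(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(1.0, 0.05, 10), rng.normal(0.2, 0.05, 10)])
        cps = detect_changepoints(x)
        k, _ = exhaustive_split_oracle(x)
        assert [c.index for c in cps] == [k]
        assert cps[0].direction == "down"

    def test_best_single_split_equals_oracle_on_random_series(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, 40)
            x[25:] += rng.uniform(0.5, 2.0)
            k1, r1 = best_single_split(x)
            k2, r2 = exhaustive_split_oracle(x)
            assert k1 == k2
            assert r1 == pytest.approx(r2)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(1.0, 0.05, 12), rng.normal(0.4, 0.05, 8)])
        fwd = [c.index for c in detect_changepoints(x)]
        rev = [len(x) - c.index for c in detect_changepoints(x[::-1])]
        assert sorted(fwd) == sorted(rev)

    def test_short_profile_skipped(self):
        assert detect_changepoints(np.ones(5), min_len=10) == []


class TestFlagging:
    def make_profile(self, values):
        n = len(values)
        return KsProfile("par000", [f"l{i}" for i in range(n)],
                         [(f"a{i}", f"b{i}") for i in range(n)], np.asarray(values))

    def test_down_segment_flagged(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(1.0, 0.05, 10), rng.normal(0.2, 0.05, 10)])
        segs = flag_converted_segments(self.make_profile(vals))
        assert len(segs) == 1
        assert segs[0].start == 10 and segs[0].mean_ks < 0.5

    def test_upward_shift_not_flagged_as_conversion(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.2, 0.05, 10), rng.normal(1.0, 0.05, 10)])
        segs = flag_converted_segments(self.make_profile(vals))
        # only the low-Ks side may be flagged; the upward segment never is
        assert all(s.mean_ks < 0.5 for s in segs)

    def test_summary_counts_testable_profiles(self):
        rng = np.random.default_rng(5)
        null = self.make_profile(rng.normal(1.0, 0.05, 30))
        short = self.make_profile(np.ones(4))
        conv = self.make_profile(
            np.concatenate([rng.normal(1.0, 0.05, 12), rng.normal(0.2, 0.05, 8)])
        )
        flagged, testable = converted_paralogon_summary([null, short, conv])
        assert testable == 2 and flagged == 1


class TestKsProfileConstruction:
    def test_profile_follows_locus_order_and_skips_singles(self):
        par = Paralogon(
            "par001", "s1", "s2",
            blocks=[ParalogousBlock("s1", "s2", (0, 3), (0, 3))],
            statuses=[
                PairStatus("par001:0000", "RETAINED_BOTH", "a0", "b0"),
                PairStatus("par001:0001", "SINGLE_COPY", "a1", None),
                PairStatus("par001:0002", "RETAINED_BOTH", "a2", "b2"),
            ],
        )
        prof = ks_profile(par, {("a0", "b0"): 0.9, ("a2", "b2"): 1.1})
        assert prof.locus_ids == ["par001:0000", "par001:0002"]
        assert prof.ks.tolist() == [0.9, 1.1]

    def test_all_single_copy_returns_none(self):
        par = Paralogon(
            "par002", "s1", "s2",
            blocks=[ParalogousBlock("s1", "s2", (0, 1), (0, 1))],
            statuses=[PairStatus("par002:0000", "SINGLE_COPY", "a0", None)],
        )
        assert ks_profile(par, {}) is None


def plant_duplicate(genome, source_id, new_id, ks, rng):
    """Insert a copy of a gene next to its source, diverged by ~ks."""
    from ohnolog.simulate import _Simulator

    src = next(g for g in genome if g.gene_id == source_id)
    sim = _Simulator.__new__(_Simulator)
    sim.rng = rng
    sim.cfg = SimConfig(omega=0.05)
    arr = C.encode_cds(src.cds)
    sim._evolve_seq(arr, ks)
    dup = GeneModel(new_id, src.species, src.scaffold, src.rank, "+",
                    C.decode_cds(arr), C.translate(arr), src.fpkm, src.category)
    out = []
    for g in genome:
        if g.scaffold == src.scaffold and g.rank > src.rank:
            g = GeneModel(g.gene_id, g.species, g.scaffold, g.rank + 1, g.strand,
                          g.cds, g.protein, g.fpkm, g.category)
        out.append(g)
        if g.gene_id == source_id:
            dup = GeneModel(new_id, src.species, src.scaffold, src.rank + 1, "+",
                            dup.cds, dup.protein, dup.fpkm, dup.category)
            out.append(dup)
    return out


class TestSGD:
    def test_fresh_doubled_genome_yields_no_calls(self):
        ancestor = generate_ancestral_genome(SimConfig(n_genes=40, n_scaffolds=2, seed=6))
        doubled, _ = apply_wgd(ancestor)
        rbh = within_genome_rbh(doubled)
        paralogons = detect_paralogons(doubled, rbh)
        calls, counts = find_single_gene_duplications(doubled, rbh, paralogons)
        assert calls == []
        assert counts.removed_wgd == counts.rbh_pairs

    def test_recent_plant_found_and_old_plant_excluded_by_ks(self):
        rng = np.random.default_rng(7)
        # evolved genome: ohnolog pairs at Ks ~ 1, so a recent duplicate
        # out-competes the ohnolog for the reciprocal best hit
        from ohnolog.simulate import simulate

        cfg = SimConfig(
            n_genes=40, n_scaffolds=2, n_ingroup=2, n_outgroup=0, depth=0.5,
            wgd_stem=0.0, base_loss_rate=0.0, conversion_rate=0.0, sgd_rate=0.0,
            translocation_rate=0.0, seed=8,
        )
        genomes, _, truth = simulate(cfg)
        sp0 = truth.species[0]
        doubled = [
            GeneModel(g.gene_id.split("_", 1)[1], g.species, g.scaffold, g.rank,
                      g.strand, g.cds, g.protein, g.fpkm, g.category)
            for g in genomes[sp0]
        ]
        # young duplicate (Ks ~ 0.2) and an old one (Ks ~ 1.3)
        genome = plant_duplicate(doubled, "g00005A", "g00005A.s1", 0.2, rng)
        genome = plant_duplicate(genome, "g00020B", "g00020B.s1", 1.3, rng)
        rbh = within_genome_rbh(genome)
        paralogons = detect_paralogons(genome, rbh)
        calls, counts = find_single_gene_duplications(genome, rbh, paralogons)
        found = {(c.gene1_id, c.gene2_id) for c in calls}
        assert ("g00005A", "g00005A.s1") in found
        assert all("g00020B.s1" not in pair for pair in found)
        assert all(c.ks < 1.0 for c in calls)
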