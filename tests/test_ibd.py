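import itertools
import math

import numpy as np
import pytest

from famrisk.errors import (EnumerationBoundError, NoCommonAncestorError,
                            PedigreeError, ValidationError)
from famrisk.ibd import (count_meioses, gene_drop_sharing_mc,
                         genome_sharing_probability,
                         infer_inheritance_states, point_sharing_probability,
                         shared_segments)
from famrisk.io_formats import Individual, Locus, Pedigree, VariantRecord
from famrisk.pedigrees import (avuncular_pedigree, chain_pair_pedigree,
                               cousin_pair_pedigree, multi_branch_family,
                               nuclear_family, trio, two_branch_family)
from famrisk.synthetic import FounderModel, build_genetic_map, gene_drop

# ---------------------------------------------------------------------------
# Meiosis counting
# ---------------------------------------------------------------------------

def test_parent_child_one_meiosis():
    assert count_meioses(trio(), ["FA", "C1"])[0] == 1


def test_full_sibs_two_meioses():
    ped = nuclear_family(n_children=2)
    assert count_meioses(ped, ["C1", "C2"])[0] == 2


def test_first_cousins_four_meioses():
    # by hand on the 2-grandparent subgraph: couple->P1, couple->P2,
    # P1->A1, P2->B1
    ped = cousin_pair_pedigree(1)
    assert count_meioses(ped, ["A1", "B1"])[0] == 4


def test_avuncular_three_meioses():
    assert count_meioses(avuncular_pedigree(), ["UNC", "NEP"])[0] == 3


def test_no_common_ancestor_errors():
    ped = Pedigree("F", [Individual("A", None, None, "male"),
                         Individual("B", None, None, "female")])
    with pytest.raises(NoCommonAncestorError):
        count_meioses(ped, ["A", "B"])


def test_unknown_target_errors():
    with pytest.raises(PedigreeError):
        count_meioses(trio(), ["FA", "GHOST"])


# ---------------------------------------------------------------------------
# Point sharing probability
# ---------------------------------------------------------------------------

def test_point_parent_child_certain():
    assert point_sharing_probability(trio(), ["FA", "C1"]) == 1.0


def test_point_full_sibs():
    """Exhaustive oracle over the 16 equiprobable transmission vectors:
    sibs fail to share only when both parents' transmissions differ."""
    count = 0
    for f1, f2, m1, m2 in itertools.product((0, 1), repeat=4):
        if f1 == f2 or m1 == m2:
            count += 1
    assert count / 16 == 0.75
    ped = nuclear_family(n_children=2)
    assert point_sharing_probability(ped, ["C1", "C2"]) == pytest.approx(0.75)


def test_point_first_cousins_brute_force():
    """Independent enumeration of the six actual meioses of a cousin pair."""
    share = total = 0
    for bits in itertools.product((0, 1), repeat=6):
        fp1, mp1, fp2, mp2, a, b = bits
        # P1 haplotypes: (GF hap fp1, GM hap mp1); cousin A carries one
        p1 = [("F", fp1), ("M", mp1)]
        p2 = [("F", fp2), ("M", mp2)]
        ha, hb = p1[a], p2[b]
        total += 1
        share += ha == hb
    expected = share / total
    ped = cousin_pair_pedigree(1)
    assert expected == 0.25
    assert point_sharing_probability(ped, ["A1", "B1"]) == pytest.approx(expected)


def test_point_avuncular():
    # uncle carries 2 of the couple's 4 haplotypes, nephew exactly one:
    # P(nephew's is among the uncle's) = 1/2
    assert point_sharing_probability(
        avuncular_pedigree(), ["UNC", "NEP"]) == pytest.approx(0.5)


def test_point_halves_along_chain():
    """Each added meiosis on a chain at most halves the probability."""
    probs = []
    for depth_b in range(2, 6):
        ped = chain_pair_pedigree(2, depth_b)
        targets = ped.affected()
        probs.append(point_sharing_probability(ped, targets))
    for a, b in zip(probs, probs[1:]):
        assert b <= a / 2 + 1e-12


def test_enumeration_bound_instructs_mc():
    ped = chain_pair_pedigree(14, 14)
    with pytest.raises(EnumerationBoundError, match="gene_drop_sharing_mc"):
        point_sharing_probability(ped, ped.affected())


# ---------------------------------------------------------------------------
# Genome sharing probability
# ---------------------------------------------------------------------------

def test_genome_parent_child_certain():
    gmap = build_genetic_map([("1", 1_000_000), ("2", 2_000_000)], 35.3)
    assert genome_sharing_probability(trio(), ["FA", "C1"], gmap) == 1.0


def test_genome_binomial_vs_poisson():
    gmap = build_genetic_map([("1", 100_000_000)], 1.0)
    ped = cousin_pair_pedigree(1)
    pb = genome_sharing_probability(ped, ["A1", "B1"], gmap, tail="binomial")
    pp = genome_sharing_probability(ped, ["A1", "B1"], gmap, tail="poisson")
    assert pb == pytest.approx(1 - 0.75 ** 5)
    assert pp == pytest.approx(1 - math.exp(-0.25 * 5))
    with pytest.raises(ValidationError):
        genome_sharing_probability(ped, ["A1", "B1"], gmap, tail="bogus")


def test_genome_matches_mc_on_small_map(rng):
    ped = cousin_pair_pedigree(1)
    gmap = build_genetic_map([("1", 100_000_000)], 0.05)
    p_ana = genome_sharing_probability(ped, ["A1", "B1"], gmap)
    p_mc, se = gene_drop_sharing_mc(ped, ["A1", "B1"], gmap, 2000, rng=rng)
    assert abs(p_mc - p_ana) <= 3 * se


# ---------------------------------------------------------------------------
# Gene-drop Monte Carlo
# ---------------------------------------------------------------------------

def test_mc_parent_child_always_shares(rng, single_chrom_map):
    p, se = gene_drop_sharing_mc(trio(), ["FA", "C1"], single_chrom_map,
                                 n_sims=100, rng=rng)
    assert p == 1.0


def test_mc_sibs_single_chromosome_no_recomb(rng):
    gmap = build_genetic_map([("1", 100_000_000)], 0.0)
    ped = nuclear_family(n_children=2)
    p, se = gene_drop_sharing_mc(ped, ["C1", "C2"], gmap, 2000, rng=rng)
    # single segment: exact point probability 0.75
    assert abs(p - 0.75) <= 3 * se


def test_mc_requires_min_sims(rng, single_chrom_map):
    with pytest.raises(ValidationError):
        gene_drop_sharing_mc(trio(), ["FA", "C1"], single_chrom_map, 50,
                             rng=rng)


# ---------------------------------------------------------------------------
# Inheritance states
# ---------------------------------------------------------------------------

def _quartet_panel(gf, gm, g1, g2, n_sites=30, chrom="1"):
    from famrisk.io_formats import GenotypePanel
    loci = [Locus(f"S{i}", chrom, 1000 * (i + 1), "A", "G", 0.5)
            for i in range(n_sites)]
    counts = np.tile(np.array([[gf], [gm], [g1], [g2]], dtype=np.int8),
                     (1, n_sites))
    return GenotypePanel(["FA", "MO", "C1", "C2"], loci, counts)


def test_both_parents_homozygous_uninformative(quartet):
    panel = _quartet_panel(0, 2, 1, 1)
    tracks = infer_inheritance_states(panel, quartet)
    assert tracks == []  # no informative site at all


def test_haploidentical_paternal_segment(quartet):
    # father AB, mother AA, both children AB over many consecutive sites:
    # children share the paternal B, maternal contribution uninformative
    panel = _quartet_panel(1, 0, 1, 1)
    (track,) = infer_inheritance_states(panel, quartet)
    states = {s for _, _, s in track.segments}
    assert states == {"haploidentical_paternal"}


def test_nonidentical_votes(quartet):
    # father AB, mother AB, children AA and BB: opposite homozygotes can
    # share neither parental haplotype
    panel = _quartet_panel(1, 1, 0, 2)
    (track,) = infer_inheritance_states(panel, quartet)
    assert {s for _, _, s in track.segments} == {"nonidentical"}


def test_fewer_than_two_children_errors(single_chrom_map, rng):
    ped = trio()
    fm = FounderModel([Locus("L", "1", 100, "A", "G", 0.5)])
    panel = gene_drop(ped, single_chrom_map, fm, rng=rng).genotypes()
    with pytest.raises(PedigreeError):
        infer_inheritance_states(panel, ped)


def test_known_crossover_recovered(quartet, dense_marker_loci, rng):
    """Seeded gene drop with crossovers at known positions: every inferred
    boundary story checked within a 1 Mb tolerance window."""
    gmap = build_genetic_map([("1", 100_000_000)], 1.0)
    fm = FounderModel(dense_marker_loci)
    for _ in range(5):
        res = gene_drop(quartet, gmap, fm, rng=rng)
        true = sorted(
            x for c in ("C1", "C2") for w in ("pat", "mat")
            for x in res.crossovers[(c, w)]["1"])
        if len(true) == 0:
            continue
        tracks = infer_inheritance_states(res.genotypes(), quartet)
        bps = [b for tr in tracks for b in tr.breakpoints()]
        hits = sum(1 for t in true if any(abs(b - t) <= 1_000_000 for b in bps))
        assert hits >= 0.8 * len(true)


def test_recall_degrades_gracefully_with_error(quartet, dense_marker_loci):
    """Breakpoint recall is (weakly) monotone as genotyping error rises."""
    from famrisk.synthetic import add_genotype_errors
    gmap = build_genetic_map([("1", 100_000_000)], 1.0)
    fm = FounderModel(dense_marker_loci)
    recalls = []
    for flip in (0.0, 0.05, 0.25):
        rng = np.random.default_rng(99)
        tot = rec = 0
        for _ in range(8):
            res = gene_drop(quartet, gmap, fm, rng=rng)
            true = [x for c in ("C1", "C2") for w in ("pat", "mat")
                    for x in res.crossovers[(c, w)]["1"]]
            panel = add_genotype_errors(res.genotypes(), flip_rate=flip,
                                        rng=rng)
            tracks = infer_inheritance_states(panel, quartet)
            bps = [b for tr in tracks for b in tr.breakpoints()]
            tot += len(true)
            rec += sum(1 for t in true
                       if any(abs(b - t) <= 1_000_000 for b in bps))
        recalls.append(rec / tot)
    assert recalls[0] >= recalls[2] - 0.05  # clean beats very noisy
    assert recalls[0] > 0.9


# ---------------------------------------------------------------------------
# Rare-allele shared segments
# ---------------------------------------------------------------------------

def _rare(chrom, pos, genotypes, af=0.001):
    return VariantRecord(chrom, pos, "A", "G", 99.0, af, "missense", None,
                         genotypes)


def test_perfect_sharing_single_segment():
    variants = [_rare("1", p, {"a": 1, "b": 1, "c": 0})
                for p in (100, 200, 300, 400)]
    (seg,) = shared_segments(variants, ["a", "b"], min_support=3)
    assert (seg.start, seg.end) == (99, 400)
    assert seg.support == 4


def test_no_shared_rare_alleles_empty():
    variants = [_rare("1", 100, {"a": 1, "b": 0}),
                _rare("1", 200, {"a": 0, "b": 1})]
    assert shared_segments(variants, ["a", "b"], min_support=1) == []


def test_conflict_splits_run():
    gts_shared = {"a": 1, "b": 1}
    gts_conflict = {"a": 1, "b": 0}
    variants = [_rare("1", 100, gts_shared), _rare("1", 200, gts_shared),
                _rare("1", 300, gts_conflict),
                _rare("1", 400, gts_shared), _rare("1", 500, gts_shared)]
    segs0 = shared_segments(variants, ["a", "b"], min_support=2,
                            max_conflicts=0)
    assert [(s.start, s.end) for s in segs0] == [(99, 200), (399, 500)]
    segs1 = shared_segments(variants, ["a", "b"], min_support=2,
                            max_conflicts=1)
    assert [(s.start, s.end) for s in segs1] == [(99, 500)]


def test_common_alleles_ignored():
    variants = [_rare("1", 100, {"a": 1, "b": 1}, af=0.5)]
    assert shared_segments(variants, ["a", "b"], min_support=1) == []


def test_monotone_in_max_conflicts(rng):
    """Raising max_conflicts never shrinks any reported segment."""
    for _ in range(20):
        variants = []
        for i in range(40):
            a, b = int(rng.integers(2)), int(rng.integers(2))
            variants.append(_rare("1", 100 * (i + 1), {"a": a, "b": b}))
        prev = None
        for k in range(4):
            segs = shared_segments(variants, ["a", "b"], min_support=1,
                                   max_conflicts=k)
            if prev is not None:
                for s0 in prev:
                    assert any(s.start <= s0.start and s.end >= s0.end
                               for s in segs)
            prev = segs


def test_truth_tracked_segment_detection(rng):
    """A founder haplotype descending to all targets over a region is
    detected with >=90% overlap."""
    ped = nuclear_family(n_children=3)
    gmap = build_genetic_map([("1", 50_000_000)], 0.2)
    rare = [Locus(f"R{i}", "1", 5_000_000 + i * 500_000, "C", "T", 0.001)
            for i in range(10)]
    # haplotype on both of one founder's strands: transmitted to every child
    fm = FounderModel(rare, injections=[(f"R{i}", "FA", h)
                                        for i in range(10) for h in (0, 1)])
    targets = ["C1", "C2", "C3"]
    true_start, true_end = 5_000_000 - 1, 5_000_000 + 9 * 500_000
    from famrisk.io_formats import variants_from_panel
    for _ in range(5):
        res = gene_drop(ped, gmap, fm, rng=rng)
        variants = variants_from_panel(res.genotypes())
        segs = shared_segments(variants, targets, min_support=3, max_af=0.03)
        overlap = sum(max(0, min(s.end, true_end) - max(s.start, true_start))
                      for s in segs)
        assert overlap >= 0.9 * (true_end - true_start)


def test_fewer_than_two_targets_rejected():
    with pytest.raises(ValidationError):
        shared_segments([], ["a"])


# ---------------------------------------------------------------------------
# Deep family shapes
# ---------------------------------------------------------------------------

def test_two_branch_family_meioses():
    ped = two_branch_family()
    m, _ = count_meioses(ped, ped.affected())
    assert m == 15


def test_multi_branch_family_meioses():
    ped = multi_branch_family()
    m, _ = count_meioses(ped, ped.affected())
    assert m == 18
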