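import pytest

from famrisk.errors import ValidationError
from famrisk.filtering import (FilterConfig, classify_zygosity,
                               filter_variants, pair_compound_hets,
                               restrict_targets, write_candidates_tsv)
from famrisk.io_formats import (GenePanel, Individual, Pedigree,
                                VariantRecord)

PANEL = GenePanel({"G0": 0, "G1": 1, "G2": 2, "G3": 3})


def _family5_like():
    """Two parents, three affected children, one unaffected child."""
    return Pedigree("FAM", [
        Individual("FA", None, None, "male", "unaffected"),
        Individual("MO", None, None, "female", "unaffected"),
        Individual("A1", "FA", "MO", "male", "CD"),
        Individual("A2", "FA", "MO", "female", "CD"),
        Individual("A3", "FA", "MO", "male", "CD"),
        Individual("U1", "FA", "MO", "female", "unaffected"),
    ])


def _var(pos=100, qual=99.0, af=0.0, csq="missense", gene="G1", gts=None,
         chrom="1", ref="A", alt="G"):
    gts = gts or {}
    base = {"FA": 0, "MO": 0, "A1": 0, "A2": 0, "A3": 0, "U1": 0}
    base.update(gts)
    return VariantRecord(chrom, pos, ref, alt, qual, af, csq, gene, base)


def _cfg(**kw):
    kw.setdefault("required_carriers", frozenset({"A1", "A2", "A3"}))
    return FilterConfig(**kw)


HET_ALL = {"A1": 1, "A2": 1, "A3": 1}


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def test_quality_boundary_just_below():
    ped = _family5_like()
    v = _var(qual=34.0, gts=HET_ALL)
    assert filter_variants([v], PANEL, _cfg(), ped) == []
    v = _var(qual=35.0, gts=HET_ALL)
    assert len(filter_variants([v], PANEL, _cfg(), ped)) == 1


def test_trim11_shaped_candidate():
    """Novel missense variant in a distance-1 gene, het in all three
    affecteds and absent in unaffecteds -> candidate."""
    ped = _family5_like()
    v = _var(af=0.0, gene="G1", gts=HET_ALL)
    (call,) = filter_variants([v], PANEL, _cfg(), ped)
    assert call.zygosity_class == "het"
    assert call.gene_distance == 1
    assert [c for c, aff in call.carriers if aff] == ["A1", "A2", "A3"]


def test_six_variant_truth_table():
    """Hand-checked: exactly 2 of 6 variants satisfy all four clauses."""
    ped = _family5_like()
    variants = [
        _var(pos=100, gts=HET_ALL),                      # passes everything
        _var(pos=200, qual=10.0, gts=HET_ALL),           # low quality
        _var(pos=300, af=0.10, gts=HET_ALL),             # too common
        _var(pos=400, csq="noncoding_other", gts=HET_ALL),  # consequence
        _var(pos=500, gene="G3", gts=HET_ALL),           # gene too distant
        _var(pos=600, gene="G0", gts=HET_ALL),           # passes everything
    ]
    calls = filter_variants(variants, PANEL, _cfg(), ped)
    assert [c.variant.pos for c in calls] == [100, 600]


def test_required_carrier_missing_genotype_errors():
    ped = _family5_like()
    v = _var(gts=HET_ALL)
    del v.genotypes["A2"]
    with pytest.raises(ValidationError):
        filter_variants([v], PANEL, _cfg(), ped)


def test_unaffected_carriers_do_not_disqualify():
    ped = _family5_like()
    v = _var(gts={**HET_ALL, "U1": 1, "FA": 1})
    (call,) = filter_variants([v], PANEL, _cfg(), ped)
    assert ("U1", False) in call.carriers


def test_output_sorted_by_position():
    ped = _family5_like()
    variants = [_var(pos=900, chrom="2", gts=HET_ALL),
                _var(pos=100, chrom="10", gts=HET_ALL),
                _var(pos=500, chrom="2", gts=HET_ALL)]
    calls = filter_variants(variants, PANEL, _cfg(), ped)
    assert [(c.variant.chrom, c.variant.pos) for c in calls] == \
        [("2", 500), ("2", 900), ("10", 100)]


# ---------------------------------------------------------------------------
# Zygosity
# ---------------------------------------------------------------------------

def test_hom_recessive_with_het_parents():
    ped = _family5_like()
    v = _var(gts={"A1": 2, "A2": 2, "A3": 2, "FA": 1, "MO": 1})
    assert classify_zygosity(v, ped, ["A1", "A2", "A3"]) == "hom"


def test_all_het_is_het():
    ped = _family5_like()
    v = _var(gts=HET_ALL)
    assert classify_zygosity(v, ped, ["A1", "A2", "A3"]) == "het"


def test_het_with_hom_parent_stays_het():
    ped = _family5_like()
    v = _var(gts={**HET_ALL, "FA": 2})
    assert classify_zygosity(v, ped, ["A1", "A2", "A3"]) == "het"


def test_hom_with_non_het_parent_rejected():
    ped = _family5_like()
    v = _var(gts={"A1": 2, "A2": 2, "A3": 2, "FA": 0, "MO": 1})
    assert classify_zygosity(v, ped, ["A1", "A2", "A3"]) is None


def test_mixed_zygosity_unclassified():
    ped = _family5_like()
    v = _var(gts={"A1": 1, "A2": 2, "A3": 1})
    assert classify_zygosity(v, ped, ["A1", "A2", "A3"]) is None


# ---------------------------------------------------------------------------
# Compound het
# ---------------------------------------------------------------------------

def test_comp_het_trans_proven():
    ped = _family5_like()
    v1 = _var(pos=100, gts={**HET_ALL, "FA": 1, "MO": 0})
    v2 = _var(pos=200, gts={**HET_ALL, "FA": 0, "MO": 1})
    (pair,) = pair_compound_hets([v1, v2], ped, ["A1", "A2", "A3"])
    assert pair[2] == "comp_het"


def test_comp_het_unphased_single_informative_parent():
    ped = _family5_like()
    v1 = _var(pos=100, gts={**HET_ALL, "FA": 1, "MO": 1})
    v2 = _var(pos=200, gts={**HET_ALL, "FA": 1, "MO": 1})
    (pair,) = pair_compound_hets([v1, v2], ped, ["A1", "A2", "A3"])
    assert pair[2] == "comp_het_unphased"


def test_comp_het_triple_two_pairs():
    """One variant pairing with two others in the same gene -> two pairs."""
    ped = _family5_like()
    shared = {"A1": 1, "A2": 1, "A3": 1}
    v1 = _var(pos=100, gts={**shared, "FA": 1, "MO": 0})
    v2 = _var(pos=200, gts={**shared, "FA": 0, "MO": 1})
    v3 = _var(pos=300, gts={**shared, "FA": 0, "MO": 1})
    pairs = pair_compound_hets([v1, v2, v3], ped, ["A1", "A2", "A3"])
    keys = {(a.pos, b.pos) for a, b, _ in pairs}
    assert (100, 200) in keys and (100, 300) in keys
    # v2/v3 both maternal: pair exists but cannot be proven trans
    phases = {(a.pos, b.pos): ph for a, b, ph in pairs}
    assert phases[(100, 200)] == "comp_het"
    assert phases[(200, 300)] == "comp_het_unphased"


def test_comp_het_pairing_symmetric():
    ped = _family5_like()
    v1 = _var(pos=100, gts={**HET_ALL, "FA": 1, "MO": 0})
    v2 = _var(pos=200, gts={**HET_ALL, "FA": 0, "MO": 1})
    p12 = pair_compound_hets([v1, v2], ped, ["A1", "A2", "A3"])
    p21 = pair_compound_hets([v2, v1], ped, ["A1", "A2", "A3"])
    assert p12[0][2] == p21[0][2] == "comp_het"
    assert {p12[0][0].pos, p12[0][1].pos} == {p21[0][0].pos, p21[0][1].pos}


def test_comp_het_takes_precedence_over_het():
    ped = _family5_like()
    v1 = _var(pos=100, gts={**HET_ALL, "FA": 1, "MO": 0})
    v2 = _var(pos=200, gts={**HET_ALL, "FA": 0, "MO": 1})
    calls = filter_variants([v1, v2], PANEL, _cfg(), ped)
    assert sorted(c.zygosity_class for c in calls) == ["comp_het", "comp_het"]
    assert all(c.partner_variants for c in calls)


def test_comp_het_without_het_shared_model():
    ped = _family5_like()
    cfg = _cfg(zygosity_models=frozenset({"compound_het"}))
    v1 = _var(pos=100, gts={**HET_ALL, "FA": 1, "MO": 0})
    v2 = _var(pos=200, gts={**HET_ALL, "FA": 0, "MO": 1})
    calls = filter_variants([v1, v2], PANEL, cfg, ped)
    assert sorted(c.zygosity_class for c in calls) == ["comp_het", "comp_het"]
    assert all(c.partner_variants for c in calls)


# ---------------------------------------------------------------------------
# restrict_targets
# ---------------------------------------------------------------------------

def test_restrict_targets_monotone():
    ped = _family5_like()
    # carried by only 2 of 3 affecteds
    v = _var(gts={"A1": 1, "A2": 1})
    cfg = _cfg()
    assert filter_variants([v], PANEL, cfg, ped) == []
    relaxed = restrict_targets(cfg, ["A3"])
    (call,) = filter_variants([v], PANEL, relaxed, ped)
    assert call.variant.pos == 100


def test_restrict_targets_identity():
    cfg = _cfg()
    assert restrict_targets(cfg, []) is cfg


def test_restrict_targets_validation():
    cfg = _cfg()
    with pytest.raises(ValidationError):
        restrict_targets(cfg, ["NOT_A_CARRIER"])
    with pytest.raises(ValidationError):
        restrict_targets(cfg, ["A1", "A2", "A3"])


# ---------------------------------------------------------------------------
# Monotonicity & self-consistency properties
# ---------------------------------------------------------------------------

def _random_variants(rng, n=25):
    out = []
    consequences = ["missense", "splice", "noncoding_other", "promoter"]
    genes = ["G0", "G1", "G2", "G3", None]
    for i in range(n):
        gts = {s: int(rng.integers(0, 3))
               for s in ("FA", "MO", "A1", "A2", "A3", "U1")}
        out.append(_var(pos=100 * (i + 1),
                        qual=float(rng.integers(0, 60)),
                        af=float(rng.random() * 0.08),
                        csq=consequences[int(rng.integers(4))],
                        gene=genes[int(rng.integers(5))],
                        gts=gts))
    return out


def test_relaxing_thresholds_never_removes_candidates(rng):
    ped = _family5_like()
    for _ in range(10):
        variants = _random_variants(rng)
        base = _cfg(min_quality=35, max_af=0.03, max_gene_distance=1)
        keys0 = {c.variant.key
                 for c in filter_variants(variants, PANEL, base, ped)}
        for relaxed in (
            _cfg(min_quality=20, max_af=0.03, max_gene_distance=1),
            _cfg(min_quality=35, max_af=0.06, max_gene_distance=1),
            _cfg(min_quality=35, max_af=0.03, max_gene_distance=3),
        ):
            keys1 = {c.variant.key
                     for c in filter_variants(variants, PANEL, relaxed, ped)}
            assert keys0 <= keys1


def test_emitted_candidates_satisfy_all_clauses(rng):
    ped = _family5_like()
    cfg = _cfg()
    for _ in range(10):
        for call in filter_variants(_random_variants(rng), PANEL, cfg, ped):
            v = call.variant
            assert v.quality >= cfg.min_quality
            assert v.pop_af <= cfg.max_af
            assert v.consequence in cfg.consequences
            assert PANEL.distance(v.gene) <= cfg.max_gene_distance
            for t in cfg.required_carriers:
                assert v.genotypes[t] in (1, 2)


# ---------------------------------------------------------------------------
# Config validation & output
# ---------------------------------------------------------------------------

def test_filter_config_validation():
    with pytest.raises(ValidationError):
        FilterConfig(required_carriers=frozenset())
    with pytest.raises(ValidationError):
        _cfg(max_af=1.5)
    with pytest.raises(ValidationError):
        _cfg(min_quality=-1)
    with pytest.raises(ValidationError):
        _cfg(consequences=frozenset({"bogus"}))


def test_candidates_tsv(tmp_path):
    ped = _family5_like()
    v = _var(gts=HET_ALL)
    calls = filter_variants([v], PANEL, _cfg(), ped)
    out = tmp_path / "cands.tsv"
    write_candidates_tsv(calls, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("chrom\tpos")
    assert "Het" in lines[1]
    assert "A1,A2,A3" in lines[1]
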