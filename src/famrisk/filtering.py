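"""Rare candidate-variant filtering for multiply-affected families.

A variant survives when it passes site-level filters (quality, population
allele frequency, functional consequence, gene-panel distance), is carried by
every required affected individual, and fits at least one enabled zygosity
model: shared heterozygous, homozygous-recessive (parents heterozygous), or
compound-heterozygous (two variants in one gene in trans).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .errors import ValidationError
from .io_formats import (CONSEQUENCES, GenePanel, Pedigree, VariantRecord,
                         _chrom_sort_key)

__all__ = [
    "FilterConfig",
    "CandidateCall",
    "filter_variants",
    "classify_zygosity",
    "pair_compound_hets",
    "restrict_targets",
    "write_candidates_tsv",
]

DEFAULT_CONSEQUENCES = frozenset(
    {"loss_of_function", "missense", "splice", "mirna_binding",
     "promoter", "enhancer"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and zygosity models for the candidate cascade."""

    required_carriers: frozenset[str]
    min_quality: float = 35.0
    max_af: float = 0.03
    consequences: frozenset[str] = DEFAULT_CONSEQUENCES
    max_gene_distance: int = 2
    excluded: frozenset[str] = frozenset()
    zygosity_models: frozenset[str] = frozenset({"het_shared", "hom_recessive",
                                                 "compound_het"})
    cross_gene_comp_het: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_carriers",
                           frozenset(self.required_carriers))
        object.__setattr__(self, "consequences", frozenset(self.consequences))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        object.__setattr__(self, "zygosity_models",
                           frozenset(self.zygosity_models))
        if not self.required_carriers:
            raise ValidationError("required_carriers must be non-empty")
        if not (0.0 <= self.max_af <= 1.0):
            raise ValidationError("max_af must be in [0,1]")
        if self.min_quality < 0:
            raise ValidationError("min_quality must be >= 0")
        if self.max_gene_distance < 0:
            raise ValidationError("max_gene_distance must be >= 0")
        bad = self.consequences - set(CONSEQUENCES)
        if bad:
            raise ValidationError(f"unknown consequences {sorted(bad)}")
        bad = self.zygosity_models - {"het_shared", "hom_recessive",
                                      "compound_het"}
        if bad:
            raise ValidationError(f"unknown zygosity models {sorted(bad)}")


@dataclass(frozen=True)
class CandidateCall:
    """A surviving variant with its zygosity class and carrier annotation."""

    variant: VariantRecord
    family_id: str
    zygosity_class: str  # het | hom | comp_het | comp_het_unphased
    carriers: tuple[tuple[str, bool], ...]  # (iid, affected?)
    gene_distance: int
    partner_variants: tuple[tuple[str, int, str, str], ...] = ()
    method: str = "genome-wide"

    def __post_init__(self) -> None:
        if self.zygosity_class in ("comp_het", "comp_het_unphased") \
                and not self.partner_variants:
            raise ValidationError("compound-het call needs >=1 partner")


def restrict_targets(config: FilterConfig,
                     exclude_ids: Sequence[str]) -> FilterConfig:
    """Drop individuals from ``required_carriers`` (e.g. to restrict the
    analysis to one subtype); candidate sets can only grow."""
    exclude = frozenset(exclude_ids)
    extra = exclude - config.required_carriers
    if extra:
        raise ValidationError(f"not required carriers: {sorted(extra)}")
    remaining = config.required_carriers - exclude
    if not remaining:
        raise ValidationError("cannot exclude every required carrier")
    if not exclude:
        return config
    return replace(config, required_carriers=remaining)


def _site_pass(v: VariantRecord, panel: GenePanel, config: FilterConfig) -> bool:
    if v.quality < config.min_quality:
        return False
    if v.pop_af > config.max_af:
        return False
    if v.consequence not in config.consequences:
        return False
    d = panel.distance(v.gene)
    if d is None or d > config.max_gene_distance:
        return False
    return True


def _required_all_carry(v: VariantRecord, config: FilterConfig) -> bool:
    for iid in config.required_carriers:
        if iid not in v.genotypes:
            raise ValidationError(
                f"required carrier {iid!r} has no genotype at "
                f"{v.chrom}:{v.pos}")
        if v.genotypes[iid] in (None, 0):
            return False
    return True


def classify_zygosity(variant: VariantRecord, pedigree: Pedigree,
                      required: Sequence[str]) -> str | None:
    """``het`` when every required affected is heterozygous; ``hom`` when all
    are homozygous-alt while every genotyped parent is heterozygous;
    otherwise ``None`` (compound-het pairing is handled separately)."""
    gts = [variant.genotypes.get(i) for i in required]
    if all(g == 1 for g in gts):
        return "het"
    if all(g == 2 for g in gts):
        for iid in required:
            for p in pedigree.parents_of(iid):
                if p is None:
                    continue
                gp = variant.genotypes.get(p)
                if gp is not None and gp != 1:
                    return None
        return "hom"
    return None


def pair_compound_hets(candidates: Sequence[VariantRecord], pedigree: Pedigree,
                       required: Sequence[str]
                       ) -> list[tuple[VariantRecord, VariantRecord, str]]:
    """Pair heterozygous candidates of one gene into compound-het calls.

    Two variants pair when every required affected carries both. Trans phase
    is proven when some affected has both parents genotyped with one parent
    carrying exactly one variant and the other parent exactly the other;
    proven pairs get class ``comp_het``, the rest ``comp_het_unphased``.
    Pairing is symmetric.
    """
    pairs: list[tuple[VariantRecord, VariantRecord, str]] = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            v1, v2 = candidates[i], candidates[j]
            if not all(v1.genotypes.get(t) not in (None, 0)
                       and v2.genotypes.get(t) not in (None, 0)
                       for t in required):
                continue
            phase = "comp_het_unphased"
            for t in required:
                fa, mo = pedigree.parents_of(t)
                if fa is None or mo is None:
                    continue
                g1f, g2f = v1.genotypes.get(fa), v2.genotypes.get(fa)
                g1m, g2m = v1.genotypes.get(mo), v2.genotypes.get(mo)
                if None in (g1f, g2f, g1m, g2m):
                    continue
                f1, f2 = g1f > 0, g2f > 0
                m1, m2 = g1m > 0, g2m > 0
                if (f1 and not f2 and m2 and not m1) or \
                        (f2 and not f1 and m1 and not m2):
                    phase = "comp_het"
                    break
            pairs.append((v1, v2, phase))
    return pairs


def filter_variants(variants: Sequence[VariantRecord], gene_panel: GenePanel,
                    config: FilterConfig, pedigree: Pedigree,
                    method: str = "genome-wide") -> list[CandidateCall]:
    """Run the full candidate cascade; output sorted by (chrom, pos)."""
    required = sorted(config.required_carriers - config.excluded)
    affected = set(pedigree.affected())

    surviving = [v for v in variants if _site_pass(v, gene_panel, config)
                 and _required_all_carry(v, config)]

    calls: list[CandidateCall] = []

    def carrier_tuple(v: VariantRecord) -> tuple[tuple[str, bool], ...]:
        return tuple((iid, iid in affected) for iid in sorted(v.carriers()))

    # compound-het pairing first: a paired variant is reported with the more
    # informative comp-het class rather than as a plain shared-het call
    claimed: set[tuple[str, int, str, str]] = set()
    if "compound_het" in config.zygosity_models:
        by_gene: dict[str, list[VariantRecord]] = {}
        for v in surviving:
            if v.gene is not None and all(
                    v.genotypes.get(t) == 1 for t in required):
                by_gene.setdefault(v.gene, []).append(v)
        groups = [vs for vs in by_gene.values() if len(vs) >= 2]
        if config.cross_gene_comp_het:
            pooled = [v for vs in by_gene.values() for v in vs]
            if len(pooled) >= 2:
                groups = [pooled]
        emitted: set[tuple] = set()
        for vs in groups:
            for v1, v2, phase in pair_compound_hets(vs, pedigree, required):
                for v, partner in ((v1, v2), (v2, v1)):
                    key = (v.key, partner.key)
                    if key in emitted:
                        continue
                    emitted.add(key)
                    claimed.add(v.key)
                    calls.append(CandidateCall(
                        variant=v, family_id=pedigree.family_id,
                        zygosity_class=phase, carriers=carrier_tuple(v),
                        gene_distance=gene_panel.distance(v.gene),  # type: ignore[arg-type]
                        partner_variants=(partner.key,), method=method))

    if "het_shared" in config.zygosity_models or \
            "hom_recessive" in config.zygosity_models:
        for v in surviving:
            if v.key in claimed:
                continue
            z = classify_zygosity(v, pedigree, required)
            if z == "het" and "het_shared" not in config.zygosity_models:
                z = None
            if z == "hom" and "hom_recessive" not in config.zygosity_models:
                z = None
            if z is None:
                continue
            calls.append(CandidateCall(
                variant=v, family_id=pedigree.family_id, zygosity_class=z,
                carriers=carrier_tuple(v),
                gene_distance=gene_panel.distance(v.gene),  # type: ignore[arg-type]
                method=method))

    calls.sort(key=lambda c: (_chrom_sort_key(c.variant.chrom), c.variant.pos,
                              c.variant.alt, c.zygosity_class))
    # merge duplicate comp-het rows for the same variant (multiple partners)
    merged: dict[tuple, CandidateCall] = {}
    for c in calls:
        k = (c.variant.key, c.zygosity_class)
        if k in merged:
            prev = merged[k]
            merged[k] = replace(prev, partner_variants=tuple(
                dict.fromkeys(prev.partner_variants + c.partner_variants)))
        else:
            merged[k] = c
    return list(merged.values())


_ZYG_LABEL = {"het": "Het", "hom": "Hom", "comp_het": "Comp-het",
              "comp_het_unphased": "Comp-het?"}


def write_candidates_tsv(calls: Sequence[CandidateCall],
                         path: str | Path) -> None:
    """Write candidate calls as a TSV with carriers and affected markers."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tfamily\tzygosity\tpartners\t"
                 "carriers\taffected_carriers\tpop_af\tdistance\tmethod\n")
        for c in calls:
            v = c.variant
            partners = ";".join(f"{p[0]}:{p[1]}:{p[2]}>{p[3]}"
                                for p in c.partner_variants)
            carriers = ",".join(i for i, _ in c.carriers)
            aff = ",".join(i for i, a in c.carriers if a)
            fh.write("\t".join([
                v.chrom, str(v.pos), v.ref, v.alt, v.gene or ".",
                c.family_id, _ZYG_LABEL[c.zygosity_class], partners or ".",
                carriers, aff or ".", f"{v.pop_af:.6g}",
                str(c.gene_distance), c.method]) + "\n")
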