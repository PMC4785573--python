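"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions are strict throughout the package:

* VCF and all user-facing variant positions are 1-based.
* All interval types (``SharedSegment``, BED output) are 0-based half-open.

The module also defines the shared domain types (pedigrees, variant records,
locus weights, genotype panels) used by the analysis modules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, PedigreeError, ValidationError, VcfFormatError

__all__ = [
    "AFFECTION_CODES",
    "CONSEQUENCES",
    "Individual",
    "Pedigree",
    "VariantRecord",
    "LocusWeight",
    "SharedSegment",
    "GenePanel",
    "Locus",
    "GenotypePanel",
    "read_pedigree",
    "write_pedigree",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_locus_weights",
    "write_locus_weights",
    "read_gene_panel",
    "write_gene_panel",
    "panel_from_variants",
    "variants_from_panel",
]

#: Allowed affection labels; PED column 6 is mapped onto these.
AFFECTION_CODES = ("unaffected", "CD", "UC", "unknown")

#: Functional consequence vocabulary used by the candidate filter.
CONSEQUENCES = (
    "loss_of_function",
    "missense",
    "splice",
    "mirna_binding",
    "promoter",
    "enhancer",
    "noncoding_other",
)

_PED_AFFECTION = {"1": "unaffected", "2": "CD", "3": "UC", "0": "unknown", "-9": "unknown"}
_PED_AFFECTION_INV = {"unaffected": "1", "CD": "2", "UC": "3", "unknown": "0"}
_PED_SEX = {"1": "male", "2": "female", "0": "unknown"}
_PED_SEX_INV = {"male": "1", "female": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father``/``mother`` are ``None`` for founders."""

    iid: str
    father: str | None
    mother: str | None
    sex: str = "unknown"
    affection: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"bad sex {self.sex!r} for {self.iid}")
        if self.affection not in AFFECTION_CODES:
            raise ValidationError(f"bad affection {self.affection!r} for {self.iid}")

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None

    @property
    def is_affected(self) -> bool:
        return self.affection in ("CD", "UC")


@dataclass
class Pedigree:
    """A single family: members in file order plus the sequenced subset."""

    family_id: str
    members: list[Individual]
    sequenced: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequenced:
            self.sequenced = {m.iid for m in self.members}
        self.validate()

    # -- accessors ---------------------------------------------------------
    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self._index[iid]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def _index(self) -> dict[str, Individual]:
        return {m.iid: m for m in self.members}

    def ids(self) -> list[str]:
        return [m.iid for m in self.members]

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def affected(self, subtype: str | None = None) -> list[str]:
        if subtype is None:
            return [m.iid for m in self.members if m.is_affected]
        return [m.iid for m in self.members if m.affection == subtype]

    def children_of(self, iid: str) -> list[str]:
        return [m.iid for m in self.members if iid in (m.father, m.mother)]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        m = self._index[iid]
        return m.father, m.mother

    def topological_order(self) -> list[Individual]:
        """Members ordered parents-before-children."""
        order: list[Individual] = []
        placed: set[str] = set()
        pending = list(self.members)
        while pending:
            progressed = False
            rest = []
            for m in pending:
                ready = all(p is None or p in placed for p in (m.father, m.mother))
                if ready:
                    order.append(m)
                    placed.add(m.iid)
                    progressed = True
                else:
                    rest.append(m)
            if not progressed:  # cycle; validate() should have caught this
                raise PedigreeError(f"cyclic parentage in family {self.family_id}")
            pending = rest
        return order

    def ancestors(self, iid: str) -> set[str]:
        """All strict ancestors of ``iid``."""
        out: set[str] = set()
        stack = [p for p in self.parents_of(iid) if p is not None]
        while stack:
            a = stack.pop()
            if a in out:
                continue
            out.add(a)
            stack.extend(p for p in self.parents_of(a) if p is not None)
        return out

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx = self._index
        if len(idx) != len(self.members):
            raise PedigreeError(f"duplicate individual ids in family {self.family_id}")
        for m in self.members:
            for p in (m.father, m.mother):
                if p is not None and p not in idx:
                    raise PedigreeError(
                        f"{m.iid} names parent {p!r} absent from family {self.family_id}"
                    )
        for m in self.members:
            if m.iid in self.ancestors(m.iid):
                raise PedigreeError(f"{m.iid} is its own ancestor")
        unknown = self.sequenced - set(idx)
        if unknown:
            raise PedigreeError(f"sequenced ids not in family: {sorted(unknown)}")


def read_pedigree(path: str | Path, family_id: str | None = None,
                  sequenced: Iterable[str] | None = None) -> Pedigree:
    """Read a six-column PED/FAM file into a validated :class:`Pedigree`.

    Column 6 uses an extended affection dialect: 1=unaffected, 2=CD, 3=UC,
    0/-9=unknown. Parent id ``0`` means missing. When the file contains more
    than one family, ``family_id`` selects which one to load.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}:{ln}: expected >=6 columns, got {len(parts)}")
        rows.append((ln, parts))

    fams = sorted({p[0] for _, p in rows})
    if family_id is None:
        if len(fams) > 1:
            raise ParseError(f"{path}: multiple families {fams}; pass family_id")
        if not fams:
            raise ParseError(f"{path}: empty pedigree file")
        family_id = fams[0]

    members = []
    for ln, p in rows:
        if p[0] != family_id:
            continue
        fid, iid, fat, mot, sex, aff = p[:6]
        if sex not in _PED_SEX:
            raise ParseError(f"{path}:{ln}: unknown sex code {sex!r}")
        if aff not in _PED_AFFECTION:
            raise ParseError(f"{path}:{ln}: unknown affection code {aff!r}")
        members.append(Individual(
            iid=iid,
            father=None if fat == "0" else fat,
            mother=None if mot == "0" else mot,
            sex=_PED_SEX[sex],
            affection=_PED_AFFECTION[aff],
        ))
    if not members:
        raise ParseError(f"{path}: family {family_id!r} not found")
    return Pedigree(family_id, members,
                    set(sequenced) if sequenced is not None else set())


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write("\t".join([
                pedigree.family_id, m.iid, m.father or "0", m.mother or "0",
                _PED_SEX_INV[m.sex], _PED_AFFECTION_INV[m.affection],
            ]) + "\n")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A bi-allelic site with per-sample alt-allele counts (``None`` = missing)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    quality: float
    pop_af: float
    consequence: str = "noncoding_other"
    gene: str | None = None
    genotypes: dict[str, int | None] = field(default_factory=dict)
    variant_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >=1, got {self.pos}")
        if not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(f"pop_af out of [0,1]: {self.pop_af}")
        if self.quality < 0:
            raise ValidationError(f"negative quality: {self.quality}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"unknown consequence {self.consequence!r}")
        for s, g in self.genotypes.items():
            if g is not None and g not in (0, 1, 2):
                raise ValidationError(f"bad allele count {g!r} for {s}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g not in (None, 0)]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (int(c), "") if c.isdigit() else (10**6, c)


def read_vcf(path: str | Path, af_key: str = "AF", csq_key: str = "CSQ",
             gene_key: str = "GENE") -> list[VariantRecord]:
    """Read a VCF into bi-allelic :class:`VariantRecord` objects via cyvcf2.

    Multi-allelic rows are split into one record per alternate allele;
    per-sample counts then count that allele only. INFO key names for the
    population allele frequency, consequence class and gene are configurable.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: no samples / no GT FORMAT field")
    records: list[VariantRecord] = []
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise VcfFormatError(f"{path}: record {v.CHROM}:{v.POS} lacks GT")
        alts = list(v.ALT)
        af_raw = v.INFO.get(af_key)
        csq_raw = v.INFO.get(csq_key)
        gene = v.INFO.get(gene_key)
        gts = v.genotypes  # [[a0, a1, phased], ...]
        for k, alt in enumerate(alts, start=1):
            try:
                if af_raw is None:
                    af = 0.0
                elif isinstance(af_raw, (tuple, list, np.ndarray)):
                    af = float(af_raw[k - 1])
                else:
                    af = float(str(af_raw).split(",")[k - 1]
                               if "," in str(af_raw) else af_raw)
            except (TypeError, ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path}: malformed {af_key} at {v.CHROM}:{v.POS}: {af_raw!r}"
                ) from exc
            if isinstance(csq_raw, str) and "," in csq_raw:
                csq = csq_raw.split(",")[k - 1]
            else:
                csq = csq_raw
            genotypes: dict[str, int | None] = {}
            for s, gt in zip(samples, gts):
                alleles = [a for a in gt[:-1]]
                if any(a < 0 for a in alleles):
                    genotypes[s] = None
                else:
                    genotypes[s] = sum(1 for a in alleles if a == k)
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                pop_af=af,
                consequence=csq if csq in CONSEQUENCES else "noncoding_other",
                gene=gene,
                genotypes=genotypes,
                variant_id=v.ID if v.ID not in (None, ".") else None,
            ))
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path,
              samples: Sequence[str] | None = None, af_key: str = "AF",
              csq_key: str = "CSQ", gene_key: str = "GENE") -> None:
    """Write records as an uncompressed VCF 4.2 text file."""
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    recs = sorted(records, key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={af_key},Number=A,Type=Float,'
                 f'Description="Population allele frequency">\n')
        fh.write(f'##INFO=<ID={csq_key},Number=A,Type=String,'
                 f'Description="Consequence class">\n')
        fh.write(f'##INFO=<ID={gene_key},Number=1,Type=String,'
                 f'Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(r.chrom for r in recs):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_str = {None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for r in recs:
            info = f"{af_key}={r.pop_af:.6g};{csq_key}={r.consequence}"
            if r.gene:
                info += f";{gene_key}={r.gene}"
            fields = [r.chrom, str(r.pos), r.variant_id or ".", r.ref, r.alt,
                      f"{r.quality:g}", "PASS", info, "GT"]
            fields += [gt_str[r.genotypes.get(s)] for s in samples]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Shared segments / BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SharedSegment:
    """A 0-based half-open interval shared identical-by-descent by ``carriers``."""

    chrom: str
    start: int
    end: int
    carriers: frozenset[str]
    support: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if not self.carriers:
            raise ValidationError("segment without carriers")
        object.__setattr__(self, "carriers", frozenset(self.carriers))


def merge_segments(segments: Iterable[SharedSegment]) -> list[SharedSegment]:
    """Merge overlapping or abutting segments that have identical carrier sets."""
    by_key: dict[tuple[str, frozenset[str]], list[SharedSegment]] = {}
    for s in segments:
        by_key.setdefault((s.chrom, s.carriers), []).append(s)
    out: list[SharedSegment] = []
    for (chrom, carriers), group in by_key.items():
        group.sort(key=lambda s: s.start)
        cur = group[0]
        for s in group[1:]:
            if s.start <= cur.end:
                cur = SharedSegment(chrom, cur.start, max(cur.end, s.end),
                                    carriers, cur.support + s.support)
            else:
                out.append(cur)
                cur = s
        out.append(cur)
    out.sort(key=lambda s: (_chrom_sort_key(s.chrom), s.start))
    return out


def write_bed(segments: Sequence[SharedSegment], path: str | Path) -> None:
    """Write BED3+ lines (0-based half-open; carriers comma-joined in col 4,
    support in col 5). Overlapping identical-carrier segments are merged."""
    merged = merge_segments(segments)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcarriers\tsupport\n")
        for s in merged:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{','.join(sorted(s.carriers))}\t{s.support}\n")


def read_bed(path: str | Path) -> list[SharedSegment]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
        carriers = frozenset(parts[3].split(",")) if len(parts) > 3 else frozenset({"?"})
        support = int(parts[4]) if len(parts) > 4 else 0
        out.append(SharedSegment(parts[0], int(parts[1]), int(parts[2]),
                                 carriers, support))
    return out


# ---------------------------------------------------------------------------
# Locus weights & gene panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusWeight:
    """A risk locus with subtype-specific odds ratios (``None`` = not in list)."""

    locus_id: str
    chrom: str
    pos: int
    risk_allele: str
    or_cd: float | None = None
    or_uc: float | None = None

    def __post_init__(self) -> None:
        if self.or_cd is None and self.or_uc is None:
            raise ValidationError(f"{self.locus_id}: needs at least one odds ratio")
        for name, v in (("or_cd", self.or_cd), ("or_uc", self.or_uc)):
            if v is not None and not v > 0:
                raise ValidationError(f"{self.locus_id}: {name} must be > 0, got {v}")

    def odds_ratio(self, subtype: str) -> float | None:
        if subtype == "CD":
            return self.or_cd
        if subtype == "UC":
            return self.or_uc
        raise ValidationError(f"unknown subtype {subtype!r}")


def read_locus_weights(path: str | Path) -> list[LocusWeight]:
    """Read a TSV with columns locus_id, chrom, pos, risk_allele, or_cd, or_uc."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["locus_id", "chrom", "pos", "risk_allele", "or_cd", "or_uc"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    dupes = df["locus_id"][df["locus_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate locus_ids {sorted(set(dupes))}")
    out = []
    for row in df.itertuples(index=False):
        out.append(LocusWeight(
            locus_id=str(row.locus_id), chrom=str(row.chrom), pos=int(row.pos),
            risk_allele=str(row.risk_allele),
            or_cd=None if pd.isna(row.or_cd) else float(row.or_cd),
            or_uc=None if pd.isna(row.or_uc) else float(row.or_uc),
        ))
    return out


def write_locus_weights(weights: Sequence[LocusWeight], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tpos\trisk_allele\tor_cd\tor_uc\n")
        for w in weights:
            fh.write("\t".join([
                w.locus_id, w.chrom, str(w.pos), w.risk_allele,
                "" if w.or_cd is None else f"{w.or_cd:g}",
                "" if w.or_uc is None else f"{w.or_uc:g}",
            ]) + "\n")


@dataclass
class GenePanel:
    """Gene -> node distance to the disease concept (0 meaning direct)."""

    distances: dict[str, int]

    def __post_init__(self) -> None:
        for g, d in self.distances.items():
            if not isinstance(d, (int, np.integer)) or d < 0:
                raise ValidationError(f"{g}: distance must be a non-negative int")

    def distance(self, gene: str | None) -> int | None:
        if gene is None:
            return None
        return self.distances.get(gene)


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a TSV of (gene, distance); 'Direct'/'direct' is accepted for 0."""
    distances: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = re.split(r"\t|\s{2,}", line.strip())
        if parts[0].lower() == "gene":
            continue
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected gene<TAB>distance")
        raw = parts[1].strip().lower()
        d = 0 if raw == "direct" else int(parts[1])
        distances[parts[0]] = d
    return GenePanel(distances)


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdistance\n")
        for g in sorted(panel.distances):
            fh.write(f"{g}\t{panel.distances[g]}\n")


# ---------------------------------------------------------------------------
# Genotype panels (matrix view used by simulation and scoring)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A simulated/scored site with a population alternate-allele frequency."""

    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.af <= 1.0):
            raise ValidationError(f"{self.locus_id}: af out of [0,1]")


@dataclass
class GenotypePanel:
    """Samples x loci matrix of alt-allele counts; -1 encodes missing."""

    samples: list[str]
    loci: list[Locus]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.shape != (len(self.samples), len(self.loci)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.samples)}, {len(self.loci)})")
        ok = np.isin(self.counts, (-1, 0, 1, 2))
        if not ok.all():
            raise ValidationError("allele counts must be in {-1,0,1,2}")

    @property
    def locus_index(self) -> dict[str, int]:
        return {l.locus_id: i for i, l in enumerate(self.loci)}

    def sample_counts(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]

    def subset(self, samples: Sequence[str]) -> "GenotypePanel":
        idx = [self.samples.index(s) for s in samples]
        return GenotypePanel(list(samples), self.loci, self.counts[idx])

    def concat(self, other: "GenotypePanel") -> "GenotypePanel":
        if [l.locus_id for l in self.loci] != [l.locus_id for l in other.loci]:
            raise ValidationError("panels have different loci")
        return GenotypePanel(self.samples + other.samples, self.loci,
                             np.vstack([self.counts, other.counts]))


def panel_from_variants(records: Sequence[VariantRecord],
                        samples: Sequence[str] | None = None) -> GenotypePanel:
    """Build a :class:`GenotypePanel` from bi-allelic variant records."""
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    loci = []
    counts = np.zeros((len(samples), len(records)), dtype=np.int8)
    for j, r in enumerate(records):
        lid = r.variant_id or f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
        loci.append(Locus(lid, r.chrom, r.pos, r.ref, r.alt, r.pop_af))
        for i, s in enumerate(samples):
            g = r.genotypes.get(s)
            counts[i, j] = -1 if g is None else g
    return GenotypePanel(list(samples), loci, counts)


def variants_from_panel(panel: GenotypePanel, quality: float = 99.0,
                        consequence: str = "noncoding_other",
                        genes: Mapping[str, str] | None = None,
                        ) -> list[VariantRecord]:
    """Inverse of :func:`panel_from_variants` (quality/consequence synthesized)."""
    out = []
    for j, l in enumerate(panel.loci):
        genotypes = {
            s: (None if panel.counts[i, j] < 0 else int(panel.counts[i, j]))
            for i, s in enumerate(panel.samples)
        }
        out.append(VariantRecord(
            chrom=l.chrom, pos=l.pos, ref=l.ref, alt=l.alt, quality=quality,
            pop_af=l.af, consequence=consequence,
            gene=genes.get(l.locus_id) if genes else None,
            genotypes=genotypes, variant_id=l.locus_id,
        ))
    return out
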