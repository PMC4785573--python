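"""Synthetic family cohorts: gene-drop simulation with Poisson recombination,
founder haplotype models, locus-weight tables, liability phenotypes and
unrelated control panels.

The gene-drop engine tracks founder-haplotype labels through the pedigree, so
it doubles as the ground-truth oracle for identical-by-descent analyses:
every simulated chromosome is a mosaic of labelled founder haplotypes with
known crossover positions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import PedigreeError, ValidationError
from .io_formats import GenotypePanel, Locus, LocusWeight, Pedigree

__all__ = [
    "GRCH37_AUTOSOMES",
    "DEFAULT_RHO",
    "GeneticMap",
    "build_genetic_map",
    "FounderModel",
    "GeneDropResult",
    "gene_drop",
    "make_locus_table",
    "loci_for_weights",
    "DiseaseModel",
    "assign_phenotypes",
    "simulate_controls",
]

#: GRCh37 autosome physical lengths in bp.
GRCH37_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("1", 249250621), ("2", 243199373), ("3", 198022430), ("4", 191154276),
    ("5", 180915260), ("6", 171115067), ("7", 159138663), ("8", 146364022),
    ("9", 141213431), ("10", 135534747), ("11", 135006516), ("12", 133851895),
    ("13", 115169878), ("14", 107349540), ("15", 102531392), ("16", 90354753),
    ("17", 81195210), ("18", 78077248), ("19", 59128983), ("20", 63025520),
    ("21", 48129895), ("22", 51304566),
)

#: Genome-wide expected crossovers per meiosis.
DEFAULT_RHO = 35.3


@dataclass(frozen=True)
class GeneticMap:
    """Physical chromosomes plus a genome-wide expected crossover count,
    allocated to chromosomes proportionally to physical length."""

    chromosomes: tuple[tuple[str, int], ...]
    rho_total: float = DEFAULT_RHO

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genetic map needs >=1 chromosome")
        if any(L <= 0 for _, L in self.chromosomes):
            raise ValidationError("chromosome lengths must be positive")
        if self.rho_total < 0:
            raise ValidationError("rho_total must be >= 0")

    @property
    def total_length(self) -> int:
        return sum(L for _, L in self.chromosomes)

    @property
    def expected_crossovers(self) -> dict[str, float]:
        T = self.total_length
        return {c: self.rho_total * L / T for c, L in self.chromosomes}

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]


def build_genetic_map(chrom_lengths: Iterable[tuple[str, int]],
                      rho_total: float = DEFAULT_RHO) -> GeneticMap:
    """Build a :class:`GeneticMap`; expectations are proportional to length."""
    chroms = tuple((str(c), int(L)) for c, L in chrom_lengths)
    if sum(L for _, L in chroms) <= 0:
        raise ValidationError("zero total map length")
    return GeneticMap(chroms, float(rho_total))


# ---------------------------------------------------------------------------
# Founder haplotype model
# ---------------------------------------------------------------------------

Haplotype = tuple[str, int]  # (founder individual id, 0 or 1)


@dataclass
class FounderModel:
    """Loci with population allele frequencies plus rare-variant injections.

    ``injections`` force the alternate allele onto a specific founder
    haplotype, e.g. ``("rare1", "F1", 0)`` places the alt allele of locus
    ``rare1`` on founder F1's first haplotype (family-private variants).
    """

    loci: list[Locus]
    injections: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate locus ids in founder model")
        known = set(ids)
        for lid, _, hap in self.injections:
            if lid not in known:
                raise ValidationError(f"injection for unknown locus {lid!r}")
            if hap not in (0, 1):
                raise ValidationError("haplotype index must be 0 or 1")

    def draw_founder_alleles(self, founder_ids: Sequence[str],
                             rng: np.random.Generator) -> dict[Haplotype, np.ndarray]:
        afs = np.array([l.af for l in self.loci])
        idx = {l.locus_id: j for j, l in enumerate(self.loci)}
        alleles: dict[Haplotype, np.ndarray] = {}
        for iid in founder_ids:
            for hap in (0, 1):
                alleles[(iid, hap)] = (rng.random(len(afs)) < afs).astype(np.int8)
        for lid, iid, hap in self.injections:
            if (iid, hap) in alleles:
                alleles[(iid, hap)][idx[lid]] = 1
        return alleles


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

# A haplotype "paint" track: sorted breakpoint starts + founder-haplotype
# label per segment; segment i covers [starts[i], starts[i+1]) (last to L).
Track = tuple[tuple[int, ...], tuple[Haplotype, ...]]


def _label_at(track: Track, pos: int) -> Haplotype:
    starts, labels = track
    return labels[bisect_right(starts, pos) - 1]


def _recombine(t0: Track, t1: Track, cuts: Sequence[int], start: int) -> Track:
    """Gamete track: alternate between parental tracks at ``cuts``."""
    if not cuts:
        return t0 if start == 0 else t1
    tracks = (t0, t1)
    raw: list[tuple[int, Haplotype]] = []
    cur, b = start, 0
    for i in range(len(cuts) + 1):
        seg_end = cuts[i] if i < len(cuts) else None
        starts, labels = tracks[cur]
        j = bisect_right(starts, b) - 1
        while j < len(starts) and (seg_end is None or starts[j] < seg_end):
            raw.append((max(starts[j], b), labels[j]))
            j += 1
        if seg_end is None:
            break
        b, cur = seg_end, 1 - cur
    # drop zero-length pieces (duplicate starts: last write wins), then
    # collapse adjacent equal labels
    cs: list[int] = []
    cl: list[Haplotype] = []
    for k, (s, l) in enumerate(raw):
        if k + 1 < len(raw) and raw[k + 1][0] == s:
            continue
        if cl and cl[-1] == l:
            continue
        cs.append(s)
        cl.append(l)
    return tuple(cs), tuple(cl)


@dataclass
class GeneDropResult:
    """Phased founder-label genomes for every pedigree member."""

    pedigree: Pedigree
    gmap: GeneticMap
    founder_model: FounderModel | None
    # tracks[iid][chrom] = (maternal-slot track? no: (hap0, hap1)); hap0 is
    # the paternally inherited strand for non-founders.
    tracks: dict[str, dict[str, tuple[Track, Track]]]
    # crossovers[(child, "pat"|"mat")][chrom] = crossover positions
    crossovers: dict[tuple[str, str], dict[str, tuple[int, ...]]]

    def labels_at(self, iid: str, chrom: str, pos: int) -> tuple[Haplotype, Haplotype]:
        h0, h1 = self.tracks[iid][chrom]
        return _label_at(h0, pos), _label_at(h1, pos)

    def crossover_count(self, child: str, which: str) -> int:
        return sum(len(v) for v in self.crossovers[(child, which)].values())

    def shared_intervals(self, targets: Sequence[str]) -> list[tuple[str, int, int]]:
        """Intervals where all ``targets`` carry a common founder haplotype."""
        out: list[tuple[str, int, int]] = []
        for chrom, L in self.gmap.chromosomes:
            points = {0}
            for t in targets:
                for hap in self.tracks[t][chrom]:
                    points.update(hap[0])
            bounds = sorted(points) + [L]
            open_start: int | None = None
            for i in range(len(bounds) - 1):
                s = bounds[i]
                shared: set[Haplotype] | None = None
                for t in targets:
                    labs = set(self.labels_at(t, chrom, s))
                    shared = labs if shared is None else shared & labs
                    if not shared:
                        break
                if shared:
                    if open_start is None:
                        open_start = s
                else:
                    if open_start is not None:
                        out.append((chrom, open_start, s))
                        open_start = None
            if open_start is not None:
                out.append((chrom, open_start, L))
        return out

    def genotypes(self) -> GenotypePanel:
        """Alt-allele counts for every member at the founder-model loci."""
        if self.founder_model is None:
            raise ValidationError("gene drop was run without a founder model")
        fm = self.founder_model
        rngless = self._founder_alleles
        samples = self.pedigree.ids()
        counts = np.zeros((len(samples), len(fm.loci)), dtype=np.int8)
        by_chrom: dict[str, list[int]] = {}
        for j, l in enumerate(fm.loci):
            by_chrom.setdefault(l.chrom, []).append(j)
        for i, iid in enumerate(samples):
            for chrom, idxs in by_chrom.items():
                h0, h1 = self.tracks[iid][chrom]
                for j in idxs:
                    pos = fm.loci[j].pos
                    a = rngless[_label_at(h0, pos)][j] + rngless[_label_at(h1, pos)][j]
                    counts[i, j] = a
        return GenotypePanel(list(samples), list(fm.loci), counts)

    _founder_alleles: dict[Haplotype, np.ndarray] = field(default_factory=dict)


def gene_drop(pedigree: Pedigree, gmap: GeneticMap,
              founder_model: FounderModel | None = None,
              seed: int | None = None,
              rng: np.random.Generator | None = None) -> GeneDropResult:
    """Drop founder haplotypes through the pedigree.

    Each meiosis draws Poisson(per-chromosome expectation) crossovers at
    uniform physical positions and alternates parental strands from a fair
    starting strand. Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for m in pedigree.members:
        if (m.father is None) != (m.mother is None):
            raise PedigreeError(f"{m.iid}: non-founder must have both parents")

    exp = gmap.expected_crossovers
    tracks: dict[str, dict[str, tuple[Track, Track]]] = {}
    crossovers: dict[tuple[str, str], dict[str, tuple[int, ...]]] = {}

    def _meiosis(parent: str, child: str, which: str) -> dict[str, Track]:
        gamete: dict[str, Track] = {}
        cuts_by_chrom: dict[str, tuple[int, ...]] = {}
        for chrom, L in gmap.chromosomes:
            k = int(rng.poisson(exp[chrom]))
            cuts = tuple(sorted(int(x) for x in rng.uniform(0, L, size=k)))
            start = int(rng.integers(2))
            h0, h1 = tracks[parent][chrom]
            gamete[chrom] = _recombine(h0, h1, cuts, start)
            cuts_by_chrom[chrom] = cuts
        crossovers[(child, which)] = cuts_by_chrom
        return gamete

    for m in pedigree.topological_order():
        if m.is_founder:
            tracks[m.iid] = {
                chrom: (((0,), ((m.iid, 0),)), ((0,), ((m.iid, 1),)))
                for chrom, _ in gmap.chromosomes
            }
        else:
            pat = _meiosis(m.father, m.iid, "pat")
            mat = _meiosis(m.mother, m.iid, "mat")
            tracks[m.iid] = {chrom: (pat[chrom], mat[chrom])
                             for chrom, _ in gmap.chromosomes}

    result = GeneDropResult(pedigree, gmap, founder_model, tracks, crossovers)
    if founder_model is not None:
        founder_ids = [f.iid for f in pedigree.founders()]
        result._founder_alleles = founder_model.draw_founder_alleles(founder_ids, rng)
    return result


# ---------------------------------------------------------------------------
# Locus tables
# ---------------------------------------------------------------------------

#: Odds ratios for the three well-characterized CD loss-of-function loci
#: added on top of the common-locus lists.
NOD2_ODDS_RATIOS = (2.023, 3.500, 4.255)


def _default_or_sampler(rng: np.random.Generator) -> float:
    # mild common-variant effects, OR in ~(1.02, 1.6)
    return float(np.exp(rng.uniform(np.log(1.02), np.log(1.6))))


def make_locus_table(n_cd: int, n_uc: int, n_shared: int,
                     or_sampler: Callable[[np.random.Generator], float] | None = None,
                     include_nod2: bool = False,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> list[LocusWeight]:
    """Build a locus-weight table with ``n_cd`` CD rows, ``n_uc`` UC rows and
    ``n_shared`` rows carrying both subtype odds ratios (union size
    ``n_cd + n_uc - n_shared``). ``include_nod2`` appends three extra CD-only
    rows with odds ratios 2.023, 3.500 and 4.255."""
    if n_shared > min(n_cd, n_uc) or min(n_cd, n_uc, n_shared) < 0:
        raise ValidationError(
            f"inconsistent counts n_cd={n_cd}, n_uc={n_uc}, n_shared={n_shared}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sample = or_sampler or _default_or_sampler
    n_union = n_cd + n_uc - n_shared
    out: list[LocusWeight] = []
    alleles = ("A", "C", "G", "T")
    chrom_cycle = [c for c, _ in GRCH37_AUTOSOMES]
    for i in range(n_union):
        is_shared = i < n_shared
        is_cd = is_shared or (i < n_cd)
        chrom = chrom_cycle[i % len(chrom_cycle)]
        ref, alt = rng.choice(len(alleles), size=2, replace=False)
        out.append(LocusWeight(
            locus_id=f"L{i + 1:04d}", chrom=chrom,
            pos=1_000_000 + 50_000 * (i // len(chrom_cycle) + 1) + i,
            risk_allele=alleles[alt],
            or_cd=sample(rng) if is_cd else None,
            or_uc=sample(rng) if (is_shared or not is_cd) else None,
        ))
    if include_nod2:
        for k, oddsr in enumerate(NOD2_ODDS_RATIOS, start=1):
            out.append(LocusWeight(
                locus_id=f"NOD2_{k}", chrom="16", pos=50_700_000 + k,
                risk_allele="T", or_cd=oddsr, or_uc=None))
    return out


def loci_for_weights(weights: Sequence[LocusWeight],
                     af_range: tuple[float, float] = (0.05, 0.5),
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> list[Locus]:
    """Assign population alternate-allele frequencies to a weight table so it
    can drive the founder model; the risk allele is taken as the alt allele."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = af_range
    refs = {"A": "G", "C": "T", "G": "A", "T": "C"}
    return [
        Locus(w.locus_id, w.chrom, w.pos, refs.get(w.risk_allele, "N"),
              w.risk_allele, float(rng.uniform(lo, hi)))
        for w in weights
    ]


# ---------------------------------------------------------------------------
# Phenotypes & controls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseModel:
    """Liability stand-in: P(affected) = logistic(beta0 + beta1 * score).

    Affected individuals are labelled CD when their CD score exceeds their UC
    score (and vice versa), with a ``mix_prob`` chance of flipping the label
    so families mix subtypes.
    """

    beta0: float = -3.0
    beta1: float = 1.0
    mix_prob: float = 0.1

    def prob(self, score: np.ndarray | float) -> np.ndarray | float:
        from scipy.special import expit
        return expit(self.beta0 + self.beta1 * np.asarray(score, dtype=float))


def assign_phenotypes(scores: Sequence[float], model: DiseaseModel,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      scores_uc: Sequence[float] | None = None) -> list[str]:
    """Draw affection statuses from the liability model.

    ``scores`` drive liability (typically the CD score); when ``scores_uc``
    is given the subtype label compares the two scores, flipped with
    probability ``mix_prob``; otherwise affected individuals are all CD.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    p = np.asarray(model.prob(s))
    hit = rng.random(len(s)) < p
    out = []
    for i, affected in enumerate(hit):
        if not affected:
            out.append("unaffected")
            continue
        if scores_uc is None:
            label = "CD"
        else:
            label = "CD" if s[i] >= scores_uc[i] else "UC"
        if rng.random() < model.mix_prob:
            label = "UC" if label == "CD" else "CD"
        out.append(label)
    return out


def add_genotype_errors(panel: GenotypePanel, flip_rate: float = 0.0,
                        missing_rate: float = 0.0,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> GenotypePanel:
    """Return a copy of ``panel`` with genotyping noise: each called genotype
    independently flips to a random different value with ``flip_rate`` and is
    set missing with ``missing_rate``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = panel.counts.copy()
    called = counts >= 0
    flip = called & (rng.random(counts.shape) < flip_rate)
    shift = rng.integers(1, 3, size=counts.shape).astype(np.int8)
    counts[flip] = (counts[flip] + shift[flip]) % 3
    miss = called & (rng.random(counts.shape) < missing_rate)
    counts[miss] = -1
    return GenotypePanel(list(panel.samples), list(panel.loci), counts)


def simulate_controls(n: int, loci: Sequence[Locus],
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      prefix: str = "CTRL") -> GenotypePanel:
    """Draw ``n`` unrelated genomes at Hardy-Weinberg equilibrium per locus."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    afs = np.array([l.af for l in loci])
    counts = rng.binomial(2, afs, size=(n, len(afs))).astype(np.int8)
    samples = [f"{prefix}{i + 1:05d}" for i in range(n)]
    return GenotypePanel(samples, list(loci), counts)
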