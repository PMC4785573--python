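"""Identical-by-descent segment analysis in pedigrees.

Three layers:

* meiosis counting and exact enumeration of inheritance vectors, giving the
  probability that a set of relatives shares a common founder haplotype at a
  single genomic point;
* a genome-wide sharing model: the genome is partitioned into an expected
  ``C + m * rho`` segments (``C`` chromosomes, ``m`` meioses at ``rho``
  expected crossovers each) and the chance of at least one all-shared
  segment follows from the point probability;
* empirical detectors: inheritance-state inference for nuclear families and
  a rare-allele sharing scan, plus a gene-drop Monte-Carlo estimator that
  serves as the oracle for the analytic model.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .errors import (EnumerationBoundError, NoCommonAncestorError,
                     PedigreeError, ValidationError)
from .io_formats import (GenotypePanel, Pedigree, SharedSegment, VariantRecord)
from .synthetic import GeneticMap, gene_drop

__all__ = [
    "MeiosisGraph",
    "count_meioses",
    "point_sharing_probability",
    "genome_sharing_probability",
    "gene_drop_sharing_mc",
    "InheritanceStateTrack",
    "infer_inheritance_states",
    "shared_segments",
    "STATES",
]

#: Exact enumeration is refused above this many binary inheritance choices.
ENUMERATION_BOUND = 26

_COUPLE = "__COUPLE__"


# ---------------------------------------------------------------------------
# Meiosis graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeiosisGraph:
    """Minimal transmission subgraph connecting targets to a founder couple.

    Edges are (parent, child) transmissions with the two couple members
    merged into a single node, so full siblings are connected by two edges
    and first cousins by four.
    """

    couple: tuple[str, str]
    targets: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def m_total(self) -> int:
        return len(self.edges)


def _path_to_couple(pedigree: Pedigree, target: str,
                    couple: tuple[str, str]) -> list[tuple[str, str]] | None:
    """Shortest upward chain of (parent, child) edges from ``target`` to the
    couple (couple node merged); ``[]`` if the target is a couple member."""
    if target in couple:
        return []
    # BFS over "individual -> parent" links
    prev: dict[str, tuple[str, str]] = {}
    q = deque([target])
    seen = {target}
    while q:
        cur = q.popleft()
        for p in pedigree.parents_of(cur):
            if p is None:
                continue
            if p in couple:
                # full couple transmission only when both parents are the
                # couple; otherwise a single-member (half) transmission
                full = set(pedigree.parents_of(cur)) == set(couple)
                top = _COUPLE if full else p
                return _rebuild_path(prev, target, cur, top)
            if p not in seen:
                seen.add(p)
                prev[p] = (p, cur)
                q.append(p)
    return None


def _rebuild_path(prev: dict[str, tuple[str, str]], target: str,
                  top_child: str, top_parent: str) -> list[tuple[str, str]]:
    """Edges from the couple down to ``target`` given BFS back-pointers."""
    edges = [(top_parent, top_child)]
    node = top_child
    while node != target:
        parent, child = prev[node]
        edges.append((parent, child))
        node = child
    return edges


def count_meioses(pedigree: Pedigree, targets: Sequence[str]
                  ) -> tuple[int, MeiosisGraph]:
    """Count transmissions in the minimal subgraph connecting ``targets``
    through their closest common ancestral couple.

    Returns ``(m_total, graph)``; raises
    :class:`~famrisk.errors.NoCommonAncestorError` when no founder couple is
    ancestral to every target.
    """
    targets = tuple(dict.fromkeys(targets))
    if not targets:
        raise ValidationError("need at least one target")
    for t in targets:
        if t not in pedigree:
            raise PedigreeError(f"target {t!r} not in pedigree")

    couples = {
        (m.father, m.mother)
        for m in pedigree.members
        if m.father is not None and m.mother is not None
    }
    best: MeiosisGraph | None = None
    for couple in sorted(couples):
        paths = []
        ok = True
        for t in targets:
            p = _path_to_couple(pedigree, t, couple)
            if p is None:
                ok = False
                break
            paths.append(p)
        if not ok:
            continue
        edges = tuple(sorted({e for path in paths for e in path}))
        g = MeiosisGraph(couple, targets, edges)
        if best is None or g.m_total < best.m_total:
            best = g
    if best is None:
        raise NoCommonAncestorError(
            f"no common ancestral couple for targets {list(targets)}")
    return best.m_total, best


# ---------------------------------------------------------------------------
# Point sharing probability (exact enumeration)
# ---------------------------------------------------------------------------

def point_sharing_probability(pedigree: Pedigree, targets: Sequence[str],
                              graph: MeiosisGraph | None = None) -> float:
    """Probability that all targets carry a copy of one common haplotype of
    their closest common founder couple at a single genomic point.

    Enumerates every inheritance vector exactly: each transmission in the
    meiosis graph independently passes one of the parent's two haplotypes
    with probability 1/2 (a couple->child transmission involves one paternal
    and one maternal choice). Raises
    :class:`~famrisk.errors.EnumerationBoundError` when the number of binary
    choices exceeds ``ENUMERATION_BOUND``; use :func:`gene_drop_sharing_mc`
    then.
    """
    if graph is None:
        _, graph = count_meioses(pedigree, targets)
    targets = graph.targets

    # assign bit positions
    bit_of: dict[tuple[str, str, int], int] = {}
    n_bits = 0
    for parent, child in graph.edges:
        slots = (0, 1) if parent == _COUPLE else (0,)
        for s in slots:
            bit_of[(parent, child, s)] = n_bits
            n_bits += 1
    if n_bits > ENUMERATION_BOUND:
        raise EnumerationBoundError(
            f"{n_bits} binary inheritance choices exceed the exact bound "
            f"({ENUMERATION_BOUND}); use gene_drop_sharing_mc instead")

    idx = np.arange(1 << n_bits, dtype=np.uint32)

    def bit(b: int) -> np.ndarray:
        return ((idx >> np.uint32(b)) & np.uint32(1)).astype(bool)

    # founder couple haplotype labels 0..3; married-in haplotypes get unique
    # dummy labels >= 4; scalar labels broadcast against the vector index
    father, mother = graph.couple
    labels: dict[str, tuple] = {}
    labels[father] = (np.uint8(0), np.uint8(1))
    labels[mother] = (np.uint8(2), np.uint8(3))
    dummy = 4

    children_edges: dict[str, list[str]] = {}
    for parent, child in graph.edges:
        children_edges.setdefault(child, []).append(parent)

    # process children in topological order of the subgraph
    pending = dict(children_edges)
    while pending:
        progressed = False
        for child in list(pending):
            parents = pending[child]
            ready = all(p == _COUPLE or p in labels for p in parents)
            if not ready:
                continue
            slots: list = []
            for p in parents:
                if p == _COUPLE:
                    bf = bit(bit_of[(p, child, 0)])
                    bm = bit(bit_of[(p, child, 1)])
                    slots.append(np.where(bf, np.uint8(0), np.uint8(1)))
                    slots.append(np.where(bm, np.uint8(2), np.uint8(3)))
                else:
                    b = bit(bit_of[(p, child, 0)])
                    h0, h1 = labels[p]
                    slots.append(np.where(b, h0, h1))
            while len(slots) < 2:  # other parent married-in: unshareable
                slots.append(np.uint8(dummy))
                dummy += 1
            if len(slots) > 2:
                raise PedigreeError(f"{child}: more than two parents in graph")
            labels[child] = (slots[0], slots[1])
            del pending[child]
            progressed = True
        if not progressed:
            raise PedigreeError("meiosis graph is not acyclic")

    share = np.zeros(idx.shape, dtype=bool)
    for h in range(4):
        all_carry = np.ones(idx.shape, dtype=bool)
        for t in targets:
            h0, h1 = labels[t]
            all_carry &= (h0 == h) | (h1 == h)
            if not all_carry.any():
                break
        share |= all_carry
    return float(share.mean())


def genome_sharing_probability(pedigree: Pedigree, targets: Sequence[str],
                               gmap: GeneticMap,
                               tail: str = "binomial") -> float:
    """Probability of observing at least one genome-wide segment shared
    identical-by-descent by all targets.

    The genome is modelled as ``N = C + m * rho`` independent segments
    (``C`` chromosomes plus one breakpoint per expected crossover over the
    ``m`` connecting meioses); with point-sharing probability ``p`` the
    result is ``1 - (1 - p)**N`` (``tail="binomial"``, default) or
    ``1 - exp(-p * N)`` (``tail="poisson"``).
    """
    m, graph = count_meioses(pedigree, targets)
    p = point_sharing_probability(pedigree, targets, graph)
    n_segments = len(gmap.chromosomes) + m * gmap.rho_total
    if tail == "binomial":
        return float(1.0 - (1.0 - p) ** n_segments)
    if tail == "poisson":
        return float(1.0 - np.exp(-p * n_segments))
    raise ValidationError(f"unknown tail model {tail!r}")


def gene_drop_sharing_mc(pedigree: Pedigree, targets: Sequence[str],
                         gmap: GeneticMap, n_sims: int = 2000,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[float, float]:
    """Monte-Carlo estimate (with binomial SE) of the genome-wide sharing
    probability, by gene-dropping labelled founder haplotypes."""
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        res = gene_drop(pedigree, gmap, founder_model=None, rng=rng)
        if res.shared_intervals(list(targets)):
            hits += 1
    p = hits / n_sims
    se = float(np.sqrt(p * (1 - p) / n_sims))
    return p, se


# ---------------------------------------------------------------------------
# Inheritance-state inference (nuclear families)
# ---------------------------------------------------------------------------

STATES = ("identical", "haploidentical_paternal",
          "haploidentical_maternal", "nonidentical")


@dataclass
class InheritanceStateTrack:
    """Smoothed inheritance-state segmentation of one chromosome."""

    chrom: str
    segments: list[tuple[int, int, str]]  # 0-based half-open
    positions: np.ndarray  # informative site positions (1-based)
    site_states: list[str]  # smoothed state per informative site
    support: dict[str, int] = field(default_factory=dict)

    def breakpoints(self) -> list[int]:
        """Internal segment boundaries."""
        return [seg[0] for seg in self.segments[1:]]

    def state_at(self, pos: int) -> str | None:
        for s, e, st in self.segments:
            if s <= pos - 1 < e:
                return st
        return None


_HAPS = {0: ((0, 0),), 1: ((0, 1),), 2: ((1, 1),)}


@lru_cache(maxsize=None)
def _consistent_states(gf: int, gm: int, gc: tuple[int, ...]
                       ) -> frozenset[str]:
    """States compatible with observed genotypes of a nuclear family.

    Enumerates parental haplotype assignments and per-child transmission
    bits; a state is compatible if some assignment in its class reproduces
    every child genotype. Heterozygous parents need only one hap ordering
    since states are invariant under a global bit flip.
    """
    k = len(gc)
    out: set[str] = set()
    for fa in _HAPS[gf]:
        for mo in _HAPS[gm]:
            for pat in product((0, 1), repeat=k):
                for mat in product((0, 1), repeat=k):
                    if all(fa[pat[i]] + mo[mat[i]] == gc[i] for i in range(k)):
                        pat_same = len(set(pat)) == 1
                        mat_same = len(set(mat)) == 1
                        if pat_same and mat_same:
                            out.add("identical")
                        elif pat_same:
                            out.add("haploidentical_paternal")
                        elif mat_same:
                            out.add("haploidentical_maternal")
                        else:
                            out.add("nonidentical")
    return frozenset(out)


def _nuclear_roles(panel: GenotypePanel, pedigree: Pedigree
                   ) -> tuple[str, str, list[str]]:
    present = set(panel.samples)
    children = [m for m in pedigree.members
                if m.father in present and m.mother in present
                and m.iid in present]
    if len(children) < 2:
        raise PedigreeError("need a nuclear family with >=2 genotyped children")
    fathers = {c.father for c in children}
    mothers = {c.mother for c in children}
    if len(fathers) != 1 or len(mothers) != 1:
        raise PedigreeError("genotyped children must share both parents")
    return fathers.pop(), mothers.pop(), [c.iid for c in children]


def infer_inheritance_states(panel: GenotypePanel, pedigree: Pedigree,
                             window: int = 11) -> list[InheritanceStateTrack]:
    """Infer the inheritance-state segmentation of a nuclear family.

    Per informative site the children's allele-sharing pattern votes for the
    compatible canonical states; a sliding-window majority over ``window``
    informative sites smooths the track (ties extend the preceding state).
    Sites where both parents are homozygous carry no information. Returns
    one track per chromosome present in the panel.
    """
    father, mother, children = _nuclear_roles(panel, pedigree)
    fi = panel.samples.index(father)
    mi = panel.samples.index(mother)
    ci = [panel.samples.index(c) for c in children]
    w2 = max(0, window // 2)

    by_chrom: dict[str, list[int]] = {}
    for j, l in enumerate(panel.loci):
        by_chrom.setdefault(l.chrom, []).append(j)

    tracks: list[InheritanceStateTrack] = []
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda j: panel.loci[j].pos)
        positions: list[int] = []
        votes: list[frozenset[str]] = []
        for j in idxs:
            gf = int(panel.counts[fi, j])
            gm = int(panel.counts[mi, j])
            gc = tuple(int(panel.counts[i, j]) for i in ci)
            if gf < 0 or gm < 0 or any(g < 0 for g in gc):
                continue
            states = _consistent_states(gf, gm, gc)
            if not states or len(states) == 4:
                continue  # inconsistent site or uninformative
            positions.append(panel.loci[j].pos)
            votes.append(states)
        if not positions:
            continue

        n = len(positions)
        assigned: list[str] = []
        prev: str | None = None
        # on ties (no preceding state) prefer the state asserting the least
        # sharing, so one-sided evidence is not over-called as identical
        tie_order = ("nonidentical", "haploidentical_paternal",
                     "haploidentical_maternal", "identical")
        for i in range(n):
            lo, hi = max(0, i - w2), min(n, i + w2 + 1)
            score = {s: 0 for s in STATES}
            for v in votes[lo:hi]:
                for s in v:
                    score[s] += 1
            best = max(score.values())
            tied = [s for s in tie_order if score[s] == best]
            state = prev if prev in tied else tied[0]
            assigned.append(state)
            prev = state

        segments: list[tuple[int, int, str]] = []
        seg_start = positions[0] - 1
        cur = assigned[0]
        for i in range(1, n):
            if assigned[i] != cur:
                boundary = (positions[i - 1] + positions[i]) // 2
                segments.append((seg_start, boundary, cur))
                seg_start = boundary
                cur = assigned[i]
        segments.append((seg_start, positions[-1], cur))
        support = {s: assigned.count(s) for s in STATES}
        tracks.append(InheritanceStateTrack(
            chrom, segments, np.asarray(positions), assigned, support))
    return tracks


# ---------------------------------------------------------------------------
# Rare-allele sharing scan
# ---------------------------------------------------------------------------

def shared_segments(variants: Sequence[VariantRecord], targets: Sequence[str],
                    min_support: int = 3, max_conflicts: int = 0,
                    max_af: float = 0.03,
                    state_tracks: Iterable[InheritanceStateTrack] | None = None,
                    ) -> list[SharedSegment]:
    """Detect segments where all ``targets`` share rare alleles.

    Rare alleles (``pop_af <= max_af``) carried by every target support a
    segment; rare alleles carried by a strict, non-empty subset of targets
    conflict with it. Maximal runs with at least ``min_support`` supporting
    sites and at most ``max_conflicts`` conflicts are reported, trimmed to
    the outermost supporting sites. When inheritance-state tracks are
    supplied (nuclear families) their ``identical`` intervals override the
    rare-allele heuristic.
    """
    targets = list(dict.fromkeys(targets))
    if len(targets) < 2:
        raise ValidationError("need >=2 targets")

    if state_tracks is not None:
        out = []
        for tr in state_tracks:
            for s, e, st in tr.segments:
                if st == "identical" and e > s:
                    n_sites = int(np.sum((tr.positions - 1 >= s)
                                         & (tr.positions - 1 < e)))
                    out.append(SharedSegment(tr.chrom, s, e,
                                             frozenset(targets), n_sites))
        return out

    events: dict[str, list[tuple[int, bool]]] = {}  # chrom -> (pos, shared?)
    for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
        if v.pop_af > max_af:
            continue
        carried = [v.genotypes.get(t) for t in targets]
        n_car = sum(1 for g in carried if g not in (None, 0))
        if n_car == 0:
            continue
        events.setdefault(v.chrom, []).append((v.pos, n_car == len(targets)))

    # maximal windows holding at most max_conflicts conflicting sites,
    # bounded by the first out-of-budget conflict on either side; this makes
    # reported segments monotone in max_conflicts
    segments: list[SharedSegment] = []
    for chrom, evs in events.items():
        n = len(evs)
        conflict_idx = [i for i, (_, s) in enumerate(evs) if not s]
        m = len(conflict_idx)
        if m <= max_conflicts:
            windows = [(0, n - 1)]
        else:
            bounds = [-1, *conflict_idx, n]
            windows = []
            for j in range(m - max_conflicts + 1):
                lo = bounds[j] + 1  # just after the conflict left of window
                hi = bounds[j + max_conflicts + 1] - 1  # just before right
                if lo <= hi:
                    windows.append((lo, hi))
        seen: set[tuple[int, int]] = set()
        for lo, hi in windows:
            shared_pos = [p for p, s in evs[lo:hi + 1] if s]
            if len(shared_pos) < min_support:
                continue
            key = (shared_pos[0] - 1, shared_pos[-1])
            if key in seen:
                continue
            seen.add(key)
            segments.append(SharedSegment(chrom, key[0], key[1],
                                          frozenset(targets), len(shared_pos)))
    # drop segments wholly contained in another reported segment
    segments = [s for s in segments
                if not any(o is not s and o.chrom == s.chrom
                           and o.start <= s.start and o.end >= s.end
                           for o in segments)]
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments
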