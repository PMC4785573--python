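"""Programmatic pedigree builders used by tests, demos and the acceptance
report: nuclear families, descent chains, and the deep multi-branch shapes
with distantly related affected members that motivate shared-segment
analysis."""

from __future__ import annotations

from typing import Sequence

from .io_formats import Individual, Pedigree

__all__ = [
    "nuclear_family",
    "trio",
    "cousin_pair_pedigree",
    "chain_pair_pedigree",
    "avuncular_pedigree",
    "two_branch_family",
    "multi_branch_family",
]


def nuclear_family(family_id: str = "FAM", n_children: int = 2,
                   child_affections: Sequence[str] | None = None,
                   father_affection: str = "unaffected",
                   mother_affection: str = "unaffected") -> Pedigree:
    """Two founder parents and ``n_children`` full siblings."""
    if child_affections is None:
        child_affections = ["unaffected"] * n_children
    if len(child_affections) != n_children:
        raise ValueError("child_affections length mismatch")
    members = [
        Individual("FA", None, None, "male", father_affection),
        Individual("MO", None, None, "female", mother_affection),
    ]
    for i, aff in enumerate(child_affections, start=1):
        sex = "male" if i % 2 else "female"
        members.append(Individual(f"C{i}", "FA", "MO", sex, aff))
    return Pedigree(family_id, members)


def trio(family_id: str = "TRIO", child_affection: str = "unaffected") -> Pedigree:
    return nuclear_family(family_id, 1, [child_affection])


def _chain(members: list[Individual], top: str, depth: int, tag: str,
           affection: str = "unknown") -> str:
    """Append a descent chain of ``depth`` meioses below ``top``; at each step
    a married-in founder spouse is added. Returns the bottom individual id."""
    by_id = {m.iid: m for m in members}
    cur = top
    for d in range(1, depth + 1):
        spouse = f"{tag}S{d}"
        child = f"{tag}{d}"
        cur_sex = by_id[cur].sex
        spouse_sex = "female" if cur_sex == "male" else "male"
        sp = Individual(spouse, None, None, spouse_sex)
        members.append(sp)
        by_id[spouse] = sp
        father, mother = (cur, spouse) if cur_sex == "male" else (spouse, cur)
        ch = Individual(child, father, mother, "male" if d % 2 else "female",
                        affection if d == depth else "unknown")
        members.append(ch)
        by_id[child] = ch
        cur = child
    return cur


def cousin_pair_pedigree(degree: int = 1, family_id: str = "COUSINS") -> Pedigree:
    """First (default) or higher-degree cousins, both affected.

    ``degree`` = 1 gives first cousins (4 meioses), 2 gives second cousins
    (6 meioses), etc.
    """
    members = [
        Individual("GF", None, None, "male"),
        Individual("GM", None, None, "female"),
        Individual("P1", "GF", "GM", "male"),
        Individual("P2", "GF", "GM", "female"),
    ]
    _chain(members, "P1", degree, "A", affection="CD")
    _chain(members, "P2", degree, "B", affection="CD")
    return Pedigree(family_id, members)


def chain_pair_pedigree(depth_a: int, depth_b: int,
                        family_id: str = "CHAIN") -> Pedigree:
    """Two affected individuals at ``depth_a`` and ``depth_b`` meioses below a
    common founder couple, via two separate children of the couple."""
    if min(depth_a, depth_b) < 1:
        raise ValueError("depths must be >= 1")
    members = [
        Individual("GF", None, None, "male"),
        Individual("GM", None, None, "female"),
    ]
    for tag, depth in (("A", depth_a), ("B", depth_b)):
        members.append(Individual(f"{tag}0", "GF", "GM",
                                  "male" if tag == "A" else "female",
                                  "CD" if depth == 1 else "unknown"))
        if depth > 1:
            _chain(members, f"{tag}0", depth - 1, tag, affection="CD")
    return Pedigree(family_id, members)


def avuncular_pedigree(family_id: str = "AVUNC") -> Pedigree:
    """Affected uncle and affected nephew (3 meioses)."""
    members = [
        Individual("GF", None, None, "male"),
        Individual("GM", None, None, "female"),
        Individual("UNC", "GF", "GM", "male", "CD"),
        Individual("PAR", "GF", "GM", "female"),
        Individual("SPO", None, None, "male"),
        Individual("NEP", "SPO", "PAR", "male", "CD"),
    ]
    return Pedigree(family_id, members)


def two_branch_family(depth_a: int = 5, depth_b: int = 6,
                      affections_a: Sequence[str] = ("CD", "CD", "UC"),
                      affections_b: Sequence[str] = ("CD", "CD"),
                      family_id: str = "F1") -> Pedigree:
    """Deep pedigree with two branches joined only at a top founder couple.

    Branch A descends ``depth_a`` meioses to an affected branch head who has
    two affected children (head + children take ``affections_a``); branch B
    descends ``depth_b`` meioses to an unaffected connector whose two
    children take ``affections_b``. With the defaults the five affected
    members are connected by 5 + 2 + 6 + 2 = 15 meioses and the two branch
    heads are separated by more than 10 meioses.
    """
    if len(affections_a) != 3 or len(affections_b) != 2:
        raise ValueError("expected 3 branch-A and 2 branch-B affections")
    members = [
        Individual("GF", None, None, "male"),
        Individual("GM", None, None, "female"),
        Individual("A0", "GF", "GM", "male"),
        Individual("B0", "GF", "GM", "female"),
    ]
    head_a = _chain(members, "A0", depth_a - 1, "A", affection=affections_a[0])
    head_b = _chain(members, "B0", depth_b - 1, "B", affection="unaffected")
    members.append(Individual("ASP", None, None, "female"))
    members.append(Individual("BSP", None, None, "male"))
    members.append(Individual("AC1", head_a, "ASP", "male", affections_a[1]))
    members.append(Individual("AC2", head_a, "ASP", "female", affections_a[2]))
    members.append(Individual("BC1", "BSP", head_b, "male", affections_b[0]))
    members.append(Individual("BC2", "BSP", head_b, "female", affections_b[1]))
    return Pedigree(family_id, members)


def multi_branch_family(depths: Sequence[int] = (4, 4, 5, 5),
                        affections: Sequence[str] = ("UC", "UC", "UC", "CD"),
                        family_id: str = "F2") -> Pedigree:
    """Deep pedigree with one affected individual per branch, all branches
    joined only at a top founder couple; branch ``i`` descends ``depths[i]``
    meioses. With the defaults the four affected members are connected by
    4 + 4 + 5 + 5 = 18 meioses."""
    if len(depths) != len(affections):
        raise ValueError("depths and affections length mismatch")
    if len(depths) < 2 or min(depths) < 1:
        raise ValueError("need >=2 branches of depth >=1")
    members = [
        Individual("GF", None, None, "male"),
        Individual("GM", None, None, "female"),
    ]
    for i, (depth, aff) in enumerate(zip(depths, affections)):
        tag = chr(ord("A") + i)
        members.append(Individual(f"{tag}0", "GF", "GM",
                                  "male" if i % 2 == 0 else "female",
                                  aff if depth == 1 else "unknown"))
        if depth > 1:
            _chain(members, f"{tag}0", depth - 1, tag, affection=aff)
    return Pedigree(family_id, members)
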