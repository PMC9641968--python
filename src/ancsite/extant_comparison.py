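"""Comparison of ancestral residue combinations with extant diversity.

Every ingroup sequence contributes its residue tuple at the variable
columns; each enumerated ancestral combination is then classified as
absent (0 extant occurrences), rare (1..rare_max, default 2) or common
(more), both at the exact-residue level and after physicochemical
recoding.  Summary fractions mirror the three headline ratios of this
kind of analysis: combinations present at residue level / all
combinations; combinations absent at type level / all combinations; and,
among type-present combinations, the fraction whose type tuple is rare.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .combination_space import Combination
from .io_phylo import Alignment
from .physchem import PhyschemScheme, recode

__all__ = [
    "ExtantProfile",
    "CombinationClassification",
    "extract_profiles",
    "classify",
    "co_occurrence_report",
]


@dataclass
class ExtantProfile:
    """Residue tuples at the variable columns across ingroup sequences."""

    columns: tuple[int, ...]
    tuples: dict[str, tuple[str, ...]]  # scorable sequences only
    aggregate: Counter = field(default_factory=Counter)
    aggregate_type: Counter = field(default_factory=Counter)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    clades: dict[str, str] = field(default_factory=dict)

    @property
    def n_scorable(self) -> int:
        return len(self.tuples)


def extract_profiles(
    aln: Alignment,
    columns,
    ingroup_ids,
    clade_map: dict[str, str] | None = None,
    scheme: PhyschemScheme | None = None,
) -> ExtantProfile:
    """Extract per-sequence residue tuples at ``columns`` (1-based).

    Sequences with a gap or 'X' at any column are excluded from the
    counts and listed in the profile's exclusion report.
    """
    columns = tuple(sorted(int(c) for c in columns))
    ingroup_ids = list(ingroup_ids)
    if not ingroup_ids:
        raise ValueError("empty ingroup")
    for col in columns:
        if not 1 <= col <= aln.length:
            raise ValueError(f"column {col} outside alignment [1, {aln.length}]")
    profile = ExtantProfile(columns=columns, tuples={}, clades=dict(clade_map or {}))
    for sid in ingroup_ids:
        row = aln.row(sid)
        tup = tuple(row[c - 1] for c in columns)
        bad = [c for c, r in zip(columns, tup) if r in ("-", "X")]
        if bad:
            profile.excluded.append((sid, f"gap/unknown at column(s) {bad}"))
            continue
        profile.tuples[sid] = tup
        profile.aggregate[tup] += 1
        profile.aggregate_type[recode(tup, scheme)] += 1
    return profile


@dataclass(frozen=True)
class CombinationClassification:
    rank: int
    residues: tuple[str, ...]
    type_tuple: tuple[str, ...]
    joint: float
    residue_status: str  # absent | rare | common
    residue_count: int
    type_status: str
    type_count: int
    #: clades of the extant sequences whose *type* tuple matches
    matching_clades: tuple[str, ...]


def _status(count: int, rare_max: int) -> str:
    if count == 0:
        return "absent"
    if count <= rare_max:
        return "rare"
    return "common"


def classify(
    combos: list[Combination],
    profile: ExtantProfile,
    scheme: PhyschemScheme | None = None,
    rare_max: int = 2,
) -> tuple[list[CombinationClassification], dict]:
    """Classify each ancestral combination against extant occurrence counts.

    Returns the per-combination records and a summary dict with the
    headline fractions (denominators: combination-space size for the
    residue-present and type-absent fractions; type-present count for the
    rare-among-present fraction).
    """
    if rare_max < 1:
        raise ValueError("rare_max must be >= 1")
    ncols = len(profile.columns)
    records = []
    type_members: dict[tuple, list[str]] = {}
    for sid, tup in profile.tuples.items():
        type_members.setdefault(recode(tup, scheme), []).append(sid)
    for c in combos:
        if len(c.residues) != ncols:
            raise ValueError(
                f"combination arity {len(c.residues)} != profile columns {ncols}"
            )
        ttuple = recode(c.residues, scheme)
        rcount = profile.aggregate.get(c.residues, 0)
        tcount = profile.aggregate_type.get(ttuple, 0)
        clades = tuple(
            sorted(
                {
                    profile.clades.get(sid, "unassigned")
                    for sid in type_members.get(ttuple, [])
                }
            )
        )
        records.append(
            CombinationClassification(
                rank=c.rank,
                residues=c.residues,
                type_tuple=ttuple,
                joint=c.joint,
                residue_status=_status(rcount, rare_max),
                residue_count=rcount,
                type_status=_status(tcount, rare_max),
                type_count=tcount,
                matching_clades=clades,
            )
        )
    n = len(records)
    residue_present = sum(1 for r in records if r.residue_status != "absent")
    type_present = sum(1 for r in records if r.type_status != "absent")
    type_absent = n - type_present
    type_rare = sum(1 for r in records if r.type_status == "rare")
    summary = {
        "n_combinations": n,
        "n_scorable_sequences": profile.n_scorable,
        "n_excluded_sequences": len(profile.excluded),
        "rare_max": rare_max,
        "residue_present": residue_present,
        "residue_present_fraction": residue_present / n,
        "residue_rare": sum(1 for r in records if r.residue_status == "rare"),
        "type_absent": type_absent,
        "type_absent_fraction": type_absent / n,
        "type_present": type_present,
        "type_rare_among_present": type_rare,
        "type_rare_among_present_fraction": (type_rare / type_present) if type_present else 0.0,
    }
    return records, summary


def co_occurrence_report(
    profile: ExtantProfile, combos: list[Combination] | None = None
) -> dict[tuple, int]:
    """Counts of extant sequences carrying each residue pair.

    Keys are ``(column_i, residue_a, column_j, residue_b)`` with i < j,
    over the residue pairs appearing in ``combos`` (default: all pairs
    observed in the combinations implied by the extant tuples themselves).
    Counts are exact scans of the extant tuples.
    """
    cols = profile.columns
    if len(cols) < 2:
        raise ValueError("need at least two columns for co-occurrence")
    pairs: set[tuple] = set()
    source = (
        [c.residues for c in combos] if combos is not None else list(profile.tuples.values())
    )
    for residues in source:
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                pairs.add((cols[i], residues[i], cols[j], residues[j]))
    report: dict[tuple, int] = {}
    for (ci, ra, cj, rb) in sorted(pairs):
        ii, jj = cols.index(ci), cols.index(cj)
        report[(ci, ra, cj, rb)] = sum(
            1 for tup in profile.tuples.values() if tup[ii] == ra and tup[jj] == rb
        )
    return report
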