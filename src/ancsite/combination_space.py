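"""Enumeration of ancestral residue combinations and their joint likelihoods.

Because marginal reconstructions report per-site posteriors
independently, the joint likelihood of a residue combination across the
variable sites is the product of its member residues' posteriors,
L(combo) = prod_i p_i(a_i).  Combinations are ranked by this product;
the ratio of each joint to the top-ranked joint is reported alongside.
These are site-combination statistics only — they do not represent
overall full-length ancestral sequence likelihoods.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .site_panel import VariableSiteSet

__all__ = ["Combination", "enumerate_combinations", "combination_summary"]


@dataclass(frozen=True)
class Combination:
    """One residue tuple over the variable sites (ascending column order)."""

    residues: tuple[str, ...]
    joint: float
    ratio_to_top: float
    rank: int
    per_site: tuple[tuple[int, str, float], ...]  # (column, residue, posterior)

    @property
    def sequence(self) -> str:
        return "".join(self.residues)


def enumerate_combinations(vs: VariableSiteSet) -> list[Combination]:
    """Full cross-product of the listed states at each variable site.

    Sorted by descending joint likelihood; ties broken lexicographically
    by residue tuple.  Size is the product of the per-site state counts.
    """
    columns = vs.columns
    if not columns:
        raise ValueError("no variable sites to enumerate")
    per_site_states = []
    for col in columns:
        states = vs.variable[col]
        if not states:
            raise ValueError(f"empty state list at column {col}")
        per_site_states.append([(col, a, p) for a, p in states])

    raw = []
    for choice in itertools.product(*per_site_states):
        residues = tuple(a for _, a, _ in choice)
        joint = math.prod(p for _, _, p in choice)
        raw.append((residues, joint, choice))
    raw.sort(key=lambda item: (-item[1], item[0]))
    top = raw[0][1]
    return [
        Combination(
            residues=residues,
            joint=joint,
            ratio_to_top=joint / top,
            rank=i + 1,
            per_site=tuple(choice),
        )
        for i, (residues, joint, choice) in enumerate(raw)
    ]


def combination_summary(combos: list[Combination]) -> dict:
    """Summary statistics of an enumerated combination space.

    ``min_joint_percent`` expresses the smallest joint as a percentage;
    ``min_joint_raw`` is the same number as a bare fraction — both are
    reported because "percent" readings of joint-likelihood bounds in the
    literature are not always unit-consistent.
    """
    if not combos:
        raise ValueError("empty combination list")
    joints = [c.joint for c in combos]
    return {
        "n_combinations": len(combos),
        "max_joint": max(joints),
        "min_joint": min(joints),
        "min_joint_raw": min(joints),
        "min_joint_percent": 100.0 * min(joints),
        "max_ratio_to_top": max(c.ratio_to_top for c in combos),
        "min_ratio_to_top": min(c.ratio_to_top for c in combos),
        "ranked": [
            {
                "rank": c.rank,
                "sequence": c.sequence,
                "joint": c.joint,
                "ratio_to_top": c.ratio_to_top,
            }
            for c in combos
        ],
    }
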