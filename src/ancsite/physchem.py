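"""Physicochemical recoding of residues and residue tuples.

Residues are collapsed into seven property categories — Acidic (E, D),
Aliphatic (I, L, M, V), Amine (Q, N), Aromatic (W, Y, F), Basic (K, R),
Small Hydroxyl (S, T), Tiny (A, G) — so that radical versus conservative
differences between residue tuples can be distinguished.  Cysteine,
histidine and proline belong to none of the named categories; each
recodes to a singleton category named by its own letter, so the scheme
never asserts a similarity it has no basis for.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

from .io_phylo import AA_LETTERS

__all__ = ["PhyschemScheme", "load_scheme", "recode", "is_conservative", "UNSCORABLE"]

logger = logging.getLogger(__name__)

#: Marker emitted for gap or unknown residues in a tuple.
UNSCORABLE = "unscorable"

DISPLAY_NAMES = {
    "acidic": "Acidic",
    "aliphatic": "Aliphatic",
    "amine": "Amine",
    "aromatic": "Aromatic",
    "basic": "Basic",
    "small_hydroxyl": "Small Hydroxyl",
    "tiny": "Tiny",
}


@dataclass
class PhyschemScheme:
    """Total mapping from residue letter to category identifier."""

    mapping: dict[str, str]
    #: residues absent from the named categories, recoded as singletons
    singletons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for letter in AA_LETTERS:
            if letter not in self.mapping:
                self.mapping[letter] = letter
                self.singletons.add(letter)
        categories: dict[str, set] = {}
        for letter, cat in self.mapping.items():
            categories.setdefault(cat, set()).add(letter)
        # categories must partition the alphabet
        total = sum(len(v) for v in categories.values())
        if total != len(self.mapping):
            raise ValueError("physicochemical categories overlap")

    def category(self, residue: str) -> str:
        if residue in ("-", "X"):
            return UNSCORABLE
        try:
            cat = self.mapping[residue]
        except KeyError:
            raise ValueError(f"not an amino-acid letter: {residue!r}") from None
        if residue in self.singletons:
            logger.warning(
                "residue %s has no named physicochemical category; "
                "recoded as singleton %r",
                residue,
                cat,
            )
        return cat


def load_scheme(path=None) -> PhyschemScheme:
    """Load a residue→category scheme; default is the packaged seven-category
    scheme (E/D acidic; I/L/M/V aliphatic; Q/N amine; W/Y/F aromatic; K/R
    basic; S/T small_hydroxyl; A/G tiny; C, H, P singletons)."""
    if path is None:
        text = (
            importlib.resources.files("ancsite.data")
            .joinpath("physchem_scheme.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    mapping: dict[str, str] = {}
    header = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        residue, category = fields[0], fields[1]
        if residue in mapping:
            raise ValueError(f"residue {residue!r} listed twice in scheme")
        mapping[residue] = category
    return PhyschemScheme(mapping=mapping)


_DEFAULT: PhyschemScheme | None = None


def _default_scheme() -> PhyschemScheme:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_scheme()
    return _DEFAULT


def recode(residues: tuple, scheme: PhyschemScheme | None = None) -> tuple:
    """Elementwise recode of a residue tuple into category identifiers.

    Gap (``-``) or unknown (``X``) positions yield the :data:`UNSCORABLE`
    marker rather than raising.  Recoding is idempotent: category names
    pass through unchanged.
    """
    scheme = scheme or _default_scheme()
    out = []
    for r in residues:
        if r in scheme.mapping or r in ("-", "X"):
            out.append(scheme.category(r))
        elif r in DISPLAY_NAMES or r == UNSCORABLE or r in scheme.mapping.values():
            out.append(r)  # already a category identifier
        else:
            raise ValueError(f"not an amino-acid letter or category: {r!r}")
    return tuple(out)


def is_conservative(combo_a: tuple, combo_b: tuple, scheme: PhyschemScheme | None = None) -> bool:
    """True iff the two equal-length residue tuples recode identically."""
    if len(combo_a) != len(combo_b):
        raise ValueError(
            f"tuple lengths differ: {len(combo_a)} vs {len(combo_b)}"
        )
    return recode(combo_a, scheme) == recode(combo_b, scheme)
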