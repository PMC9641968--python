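"""Site panels, reference-coordinate mapping, and variable-site detection.

A panel is a curated set of alignment columns of structural/functional
interest (the packaged nitrogenase panel covers the 24 substrate-channel
sites of the D subunit, labeled by the corresponding Azotobacter
vinelandii NifD residues).  A panel site is "variable" in a reconstructed
ancestor when more than one residue has posterior strictly above the
threshold (default 0.10).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .io_phylo import AA_LETTERS, Alignment, StateTable

__all__ = [
    "PanelEntry",
    "SitePanel",
    "VariableSiteSet",
    "load_panel",
    "map_alignment_to_reference",
    "detect_variable_sites",
]


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class PanelEntry:
    column: int  # 1-based alignment column
    reference_label: str
    role: str
    conserved_residue: str


@dataclass
class SitePanel:
    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        cols = [e.column for e in self.entries]
        if len(set(cols)) != len(cols):
            raise PanelError("duplicate alignment columns in panel")
        for e in self.entries:
            if e.column < 1:
                raise PanelError(f"panel column {e.column} is not 1-based positive")
            if e.conserved_residue not in AA_LETTERS:
                raise PanelError(
                    f"bad conserved residue {e.conserved_residue!r} "
                    f"for column {e.column}"
                )

    @property
    def columns(self) -> list[int]:
        return [e.column for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, column: int) -> PanelEntry:
        for e in self.entries:
            if e.column == column:
                return e
        raise KeyError(f"column {column} not in panel")


def load_panel(path=None) -> SitePanel:
    """Load a tab-delimited panel file; default is the packaged 24-site
    nitrogenase substrate-channel panel."""
    if path is None:
        text = (
            importlib.resources.files("ancsite.data").joinpath("nif24_panel.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    entries = []
    header = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[:4] != ["column", "reference_label", "role", "conserved_residue"]:
                raise PanelError(f"unexpected panel header: {header}")
            continue
        entries.append(
            PanelEntry(
                column=int(fields[0]),
                reference_label=fields[1],
                role=fields[2],
                conserved_residue=fields[3],
            )
        )
    if not entries:
        raise PanelError("empty panel file")
    return SitePanel(entries=entries)


def map_alignment_to_reference(aln: Alignment, reference_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to ungapped positions of one row.

    Columns where the reference row has a gap are absent from the map;
    the mapping is strictly increasing over mapped columns.
    """
    row = aln.row(reference_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            pos += 1
            mapping[col] = pos
    return mapping


@dataclass
class VariableSiteSet:
    """Panel columns partitioned into variable and single-state sites.

    ``variable`` maps column -> [(residue, posterior), ...] for every
    residue with posterior strictly above ``threshold``, sorted by
    descending posterior; ``monomorphic`` maps the remaining panel columns
    to their single dominant (residue, posterior).
    """

    threshold: float
    variable: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    monomorphic: dict[int, tuple[str, float]] = field(default_factory=dict)
    #: states below threshold at variable sites, retained for reporting
    subthreshold: dict[int, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def columns(self) -> list[int]:
        return sorted(self.variable)


def detect_variable_sites(
    state: StateTable, panel: SitePanel, node_id: str, threshold: float = 0.10
) -> VariableSiteSet:
    """Classify each panel column as variable or single-state at a node.

    A column is variable iff at least two residues have posterior
    strictly greater than ``threshold`` (so a {0.90, 0.10} split at the
    default threshold is *not* variable).  Raising the threshold can only
    remove variable sites.
    """
    if not 0 <= threshold < 1:
        raise PanelError(f"threshold must be in [0, 1), got {threshold}")
    vs = VariableSiteSet(threshold=threshold)
    for entry in panel.entries:
        col = entry.column
        if (node_id, col) not in state:
            raise PanelError(
                f"state table lacks node {node_id!r} column {col} required by panel"
            )
        probs = state.residue_probs(node_id, col)
        ranked = sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))
        above = [(a, p) for a, p in ranked if p > threshold]
        if len(above) >= 2:
            vs.variable[col] = above
            vs.subthreshold[col] = [(a, p) for a, p in ranked if 0 < p <= threshold]
        else:
            vs.monomorphic[col] = ranked[0]
    return vs
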