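"""Readers/writers for alignments, trees and ancestral-state tables.

The pipeline works with three artifacts: a gapped protein alignment (FASTA),
a phylogeny with branch lengths (Newick), and a per-node/per-site posterior
table over the 20 amino acids (tab-delimited "state file", the dialect
written by common ASR tools).  All alignment columns are 1-based throughout
the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "AA_LETTERS",
    "AA_INDEX",
    "Alignment",
    "Phylogeny",
    "StateTable",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "root_on_outgroup",
    "mrca",
    "read_state_table",
    "write_state_table",
]

#: The 20 amino-acid one-letter codes in alphabetical order.  This is the
#: canonical state order for every probability vector in the package.
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

_VALID_CHARS = set(AA_LETTERS) | {"-", "X"}


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """An ordered, validated protein multiple sequence alignment.

    Rows are uppercase strings over the 20 amino-acid letters plus ``-``
    (gap) and ``X`` (unknown); all rows share one length.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no records")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        seen = set()
        for sid in self.ids:
            if not sid:
                raise AlignmentError("empty sequence identifier")
            if sid in seen:
                raise AlignmentError(f"duplicate sequence identifier: {sid!r}")
            seen.add(sid)
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError(f"zero-length sequence: {self.ids[0]!r}")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {length}"
                )
            for pos, ch in enumerate(row, start=1):
                if ch not in _VALID_CHARS:
                    raise AlignmentError(
                        f"invalid character {ch!r} at position {pos} "
                        f"in sequence {sid!r}"
                    )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"unknown sequence id: {seq_id!r}") from None

    def column(self, col: int) -> str:
        """Characters of 1-based alignment column ``col``, in row order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside [1, {self.length}]")
        return "".join(r[col - 1] for r in self.rows)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Lowercase letters are uppercased and the ``.`` gap dialect is
    normalized to ``-``.  Record order is preserved.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(ids=ids, rows=rows)


def write_fasta(aln: Alignment, path, wrap: int = 60) -> None:
    """Write canonical FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Trees


class TreeError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A phylogeny with branch lengths, backed by a dendropy tree.

    ``tree.seed_node`` is the root.  A tree whose seed node has more than
    two children is treated as unrooted (basal multifurcation).
    """

    tree: dendropy.Tree

    @property
    def is_rooted(self) -> bool:
        return len(self.tree.seed_node.child_nodes()) == 2

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def find_leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise TreeError(f"unknown leaf id: {label!r}")

    def clone(self) -> "Phylogeny":
        return Phylogeny(tree=self.tree.clone(depth=1))


def _check_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length: {edge.length}")


def read_newick(source) -> Phylogeny:
    """Read a Newick tree from a path or a literal Newick string."""
    text = None
    s = str(source)
    if s.lstrip().startswith("("):
        text = s
    else:
        with open(s) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    _check_lengths(tree)
    return Phylogeny(tree=tree)


def write_newick(phy: Phylogeny, path=None) -> str:
    s = phy.tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    s = s.strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def root_on_outgroup(phy: Phylogeny, outgroup) -> Phylogeny:
    """Root the tree on the branch separating ``outgroup`` from the rest.

    The separated branch's length is split equally between the two root
    children (the likelihood under a reversible model does not depend on
    the split).  Raises if the outgroup is not one side of a bipartition.
    """
    outgroup = frozenset(outgroup)
    phy = phy.clone()
    tree = phy.tree
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = outgroup - all_leaves
    if unknown:
        raise TreeError(f"outgroup leaves not in tree: {sorted(unknown)}")
    if outgroup == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    # Work on the unrooted topology so an existing root does not hide the
    # bipartition that separates the outgroup.
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()

    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = _leafset(node)
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            break
    if target is None:
        # Report the extra leaves dragged in by the smallest clade-side
        # containing the outgroup.
        best = all_leaves
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            for side in (_leafset(node), all_leaves - _leafset(node)):
                if outgroup <= side and len(side) < len(best):
                    best = side
        raise TreeError(
            "outgroup is not monophyletic in the unrooted tree; smallest "
            f"containing split also includes: {sorted(best - outgroup)}"
        )

    edge = target.edge
    elen = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(edge, length1=elen / 2.0, length2=elen / 2.0)
    tree.seed_node.edge.length = None
    return Phylogeny(tree=tree)


def mrca(phy: Phylogeny, taxa) -> dendropy.Node:
    """Most recent common ancestor of ``taxa`` on a rooted tree."""
    taxa = set(taxa)
    if not taxa:
        raise TreeError("empty taxon set")
    if not phy.is_rooted:
        raise TreeError("mrca requires a rooted tree")
    all_leaves = set(phy.leaf_labels)
    unknown = taxa - all_leaves
    if unknown:
        raise TreeError(f"unknown leaf ids: {sorted(unknown)}")
    if len(taxa) == 1:
        return phy.find_leaf(next(iter(taxa)))
    phy.tree.is_rooted = True
    phy.tree.encode_bipartitions(suppress_unifurcations=False)
    node = phy.tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise TreeError("mrca not found")
    return node


# ---------------------------------------------------------------------------
# State tables


class StateTableError(ValueError):
    pass


@dataclass
class StateTable:
    """Per-node, per-site posterior distributions over the 20 amino acids.

    ``probs[(node_id, site)]`` is a length-20 vector in :data:`AA_LETTERS`
    order.  Vectors are validated to sum to 1 within 1e-6.
    """

    probs: dict = field(default_factory=dict)
    #: renormalization events recorded at load time: (node, site, raw_sum)
    warnings: list = field(default_factory=list)

    def set(self, node_id: str, site: int, vector) -> None:
        v = np.asarray(vector, dtype=float)
        if v.shape != (20,):
            raise StateTableError("probability vector must have 20 entries")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise StateTableError(f"probability outside [0,1] at {node_id}/{site}")
        s = float(v.sum())
        if abs(s - 1.0) > 1e-6:
            raise StateTableError(
                f"probabilities for node {node_id!r} site {site} sum to {s:.6g}"
            )
        self.probs[(node_id, site)] = np.clip(v, 0.0, 1.0)

    def vector(self, node_id: str, site: int) -> np.ndarray:
        return self.probs[(node_id, site)]

    def residue_probs(self, node_id: str, site: int) -> dict:
        v = self.vector(node_id, site)
        return {a: float(v[i]) for i, a in enumerate(AA_LETTERS)}

    def nodes(self) -> list[str]:
        return sorted({n for n, _ in self.probs})

    def sites(self, node_id: str) -> list[int]:
        return sorted(s for n, s in self.probs if n == node_id)

    def __contains__(self, key) -> bool:
        return key in self.probs


def read_state_table(path) -> StateTable:
    """Read a tab-delimited state file.

    Dialect: ``#`` comment lines; a header line ``Node  Site  State  p_A …
    p_Y`` with the 20 probability columns in alphabetical one-letter order;
    one row per (node, site).  Row sums deviating from 1 by at most 1e-4
    are renormalized (and recorded in ``warnings``); larger deviations are
    an error.
    """
    table = StateTable()
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["Node", "Site", "State"] + [f"p_{a}" for a in AA_LETTERS]
                if header != expected:
                    missing = [c for c in expected if c not in header]
                    raise StateTableError(
                        f"bad state-file header; missing columns: {missing}"
                    )
                continue
            if len(fields) != 23:
                raise StateTableError(f"line {lineno}: expected 23 fields, got {len(fields)}")
            node_id, site_s = fields[0], fields[1]
            try:
                site = int(site_s)
                v = np.array([float(x) for x in fields[3:]], dtype=float)
            except ValueError as exc:
                raise StateTableError(f"line {lineno}: non-numeric cell ({exc})") from exc
            s = float(v.sum())
            if abs(s - 1.0) > 1e-4:
                raise StateTableError(
                    f"line {lineno}: probabilities sum to {s:.6g}, "
                    "deviation exceeds 1e-4"
                )
            if abs(s - 1.0) > 1e-9:
                table.warnings.append((node_id, site, s))
                v = v / s
            table.set(node_id, site, v)
    if header is None:
        raise StateTableError(f"empty state file: {path}")
    return table


def write_state_table(table: StateTable, path, provenance: str | None = None) -> None:
    """Write the tab-delimited state-file dialect read by :func:`read_state_table`."""
    buf = io.StringIO()
    from . import __version__

    buf.write(f"# ancsite {__version__} state file\n")
    if provenance:
        buf.write(f"# {provenance}\n")
    buf.write("Node\tSite\tState\t" + "\t".join(f"p_{a}" for a in AA_LETTERS) + "\n")
    for (node_id, site), v in sorted(table.probs.items()):
        top = AA_LETTERS[int(np.argmax(v))]
        cells = "\t".join(repr(float(x)) for x in v)
        buf.write(f"{node_id}\t{site}\t{top}\t{cells}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
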