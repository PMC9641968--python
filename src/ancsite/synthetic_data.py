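"""Synthetic alignments, trees and fixtures with known ground truth.

Two kinds of synthetic input are produced:

* :func:`simulate_alignment` evolves sequences down a (random or given)
  rooted tree under a reversible amino-acid model with among-site rate
  variation, recording every internal node's true sequence, so the ASR
  engine can be tested for parameter recovery.
* :func:`make_ancestor_fixture` and :func:`make_extant_fixture` build the
  desk-scale fixtures for the downstream stages: a state table for a
  nitrogenase-like ancestor over the packaged 24-site substrate-channel
  panel (five of which have 2-4 plausible ancestral states), and a small
  extant alignment with clade-structured diversity at the five variable
  columns.

All randomized functions take an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_phylo import AA_INDEX, AA_LETTERS, Alignment, Phylogeny, StateTable
from .site_panel import SitePanel, load_panel
from .substitution_models import (
    SubstitutionModel,
    build_rate_matrix,
    load_model,
    transition_probs,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "random_topology",
    "simulate_alignment",
    "make_ancestor_fixture",
    "make_extant_fixture",
    "ANCESTOR_PANEL_STATES",
    "DEFAULT_CLADE_PROFILES",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulation run.

    ``branch_scale`` is the mean of the exponential branch-length draws
    (expected substitutions/site); ``root_policy`` is ``"pi"`` (draw the
    root sequence from equilibrium) or a fixed root sequence string.
    """

    n_leaves: int = 20
    n_sites: int = 500
    model: SubstitutionModel | None = None
    branch_scale: float = 0.3
    root_policy: str = "pi"
    tree: Phylogeny | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("need at least 2 leaves")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        if self.branch_scale < 0:
            raise ValueError("branch scale must be nonnegative")
        if self.model is None:
            self.model = load_model("LG", "uniform")
        if self.root_policy != "pi":
            bad = set(self.root_policy) - set(AA_LETTERS)
            if bad or len(self.root_policy) != self.n_sites:
                raise ValueError(
                    "fixed root sequence must have n_sites valid residues"
                )


@dataclass
class GroundTruth:
    """True sequences at every node plus per-site rate categories."""

    sequences: dict[str, str]  # node label -> sequence (leaves and internals)
    site_categories: np.ndarray
    root_label: str = "N0"

    def leaf_tuples(self, columns, leaf_ids) -> dict[str, tuple]:
        return {
            sid: tuple(self.sequences[sid][c - 1] for c in columns) for sid in leaf_ids
        }


def random_topology(n_leaves: int, branch_scale: float, rng: np.random.Generator) -> Phylogeny:
    """Random rooted binary topology by successive random leaf attachment.

    Branch lengths are exponential with mean ``branch_scale``; new leaves
    attach by bisecting a uniformly chosen existing branch.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def new_leaf(i: int) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(f"t{i + 1}")
        return node

    root = tree.seed_node
    for i in range(2):
        child = new_leaf(i)
        child.edge.length = float(rng.exponential(branch_scale))
        root.add_child(child)
    for i in range(2, n_leaves):
        edges = [
            nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None
        ]
        edge = edges[rng.integers(len(edges))]
        old_child = edge.head_node
        parent = edge.tail_node
        frac = float(rng.uniform())
        upper = edge.length * frac
        lower = edge.length - upper
        mid = dendropy.Node()
        parent.remove_child(old_child)
        parent.add_child(mid)
        mid.edge.length = upper
        mid.add_child(old_child)
        old_child.edge.length = lower
        leaf = new_leaf(i)
        leaf.edge.length = float(rng.exponential(branch_scale))
        mid.add_child(leaf)
    return Phylogeny(tree=tree)


def _label_internals(phy: Phylogeny) -> None:
    n = 0
    for node in phy.tree.preorder_node_iter():
        if not node.is_leaf() and node.label is None:
            node.label = f"N{n}"
        n += 1 if not node.is_leaf() else 0


def simulate_alignment(spec: SimulationSpec) -> tuple[Alignment, Phylogeny, GroundTruth]:
    """Evolve sequences down the tree; returns alignment, tree, truth.

    Each branch evolves each site by sampling from the corresponding row
    of P(t * r_site); identical seeds give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    phy = spec.tree.clone() if spec.tree is not None else random_topology(
        spec.n_leaves, spec.branch_scale, rng
    )
    _label_internals(phy)
    rm = build_rate_matrix(model)
    cats = rng.choice(len(model.weights), size=spec.n_sites, p=model.weights)

    if spec.root_policy == "pi":
        root_states = rng.choice(20, size=spec.n_sites, p=model.pi)
    else:
        root_states = np.array([AA_INDEX[a] for a in spec.root_policy])

    sequences: dict[str, str] = {}
    states: dict = {}
    root = phy.tree.seed_node
    states[root] = root_states
    for node in phy.tree.preorder_node_iter():
        if node is not root:
            t = node.edge.length or 0.0
            parent_states = states[node.parent_node]
            child = np.empty(spec.n_sites, dtype=int)
            for k in range(len(model.rates)):
                mask = cats == k
                if not mask.any():
                    continue
                P = transition_probs(rm, t, model.rates[k])
                # vectorized row sampling via inverse-CDF per site
                cdf = np.cumsum(P[parent_states[mask]], axis=1)
                u = rng.uniform(size=mask.sum())
                child[mask] = (u[:, None] > cdf).sum(axis=1)
            states[node] = child
        label = node.taxon.label if node.is_leaf() else node.label
        sequences[label] = "".join(AA_LETTERS[s] for s in states[node])

    leaf_ids = phy.leaf_labels
    aln = Alignment(ids=leaf_ids, rows=[sequences[i] for i in leaf_ids])
    truth = GroundTruth(sequences=sequences, site_categories=cats, root_label=root.label)
    return aln, phy, truth


# ---------------------------------------------------------------------------
# Desk-scale fixtures

#: Ancestral per-site states for the packaged 24-site panel: the listed
#: (residue, posterior) pairs for the reconstructed nitrogenase-ancestor
#: node.  Five columns (348, 495, 496, 576, 603) carry 2-4 plausible
#: states; the rest are near-invariant.
ANCESTOR_PANEL_STATES: dict[int, list[tuple[str, float]]] = {
    182: [("V", 0.99998)],
    350: [("H", 0.99999)],
    497: [("Y", 0.99997)],
    493: [("R", 0.99991)],
    604: [("H", 1.0)],
    491: [("C", 1.0)],
    745: [("H", 0.99998)],
    224: [("R", 0.99912)],
    346: [("Q", 0.99995)],
    181: [("G", 0.99934)],
    347: [("S", 0.99888)],
    155: [("N", 0.99972)],
    178: [("G", 0.99994)],
    183: [("V", 0.99824)],
    345: [("S", 0.99918)],
    348: [("A", 0.29253), ("Q", 0.27519), ("L", 0.16779), ("K", 0.16716)],
    351: [("H", 0.99992)],
    354: [("N", 0.99946)],
    494: [("S", 0.99993)],
    495: [("A", 0.74242), ("M", 0.17555)],
    496: [("T", 0.79331), ("N", 0.14693)],
    576: [("G", 0.87529), ("A", 0.12413)],
    602: [("F", 1.0)],
    603: [("A", 0.47988), ("G", 0.46717)],
}

ANCESTOR_NODE_ID = "AncNif"


def make_ancestor_fixture() -> tuple[StateTable, SitePanel]:
    """State table + panel for the packaged nitrogenase ancestor fixture.

    Each row carries exactly the listed posteriors; any residual mass is
    assigned to the lexicographically first residue with no listed
    probability (so every row sums to 1 without disturbing the listed
    values).
    """
    panel = load_panel()
    table = StateTable()
    for col, listed in ANCESTOR_PANEL_STATES.items():
        v = np.zeros(20)
        for residue, p in listed:
            v[AA_INDEX[residue]] = p
        residual = 1.0 - v.sum()
        if residual > 0:
            filler = next(a for a in AA_LETTERS if v[AA_INDEX[a]] == 0.0)
            v[AA_INDEX[filler]] = residual
        table.set(ANCESTOR_NODE_ID, col, v)
    return table, panel


#: Per-clade residue frequency profiles at the five variable columns,
#: qualitatively mirroring extant nitrogenase diversity: Group I fixes
#: Leu-348/Met-495, Group II Ala-348/Ile-495, both conserve Asn-496; the
#: divergent Nif/Anf/Vnf clade is heterogeneous at all five columns.
DEFAULT_CLADE_PROFILES: dict[str, dict[int, dict[str, float]]] = {
    "NifI": {
        348: {"L": 1.0},
        495: {"M": 1.0},
        496: {"N": 1.0},
        576: {"G": 1.0},
        603: {"G": 1.0},
    },
    "NifII": {
        348: {"A": 0.8, "G": 0.1, "S": 0.05, "C": 0.05},
        495: {"I": 1.0},
        496: {"N": 1.0},
        576: {"G": 1.0},
        603: {"G": 1.0},
    },
    "Divergent": {
        348: {"A": 0.3, "Q": 0.2, "K": 0.2, "L": 0.3},
        495: {"A": 0.5, "M": 0.5},
        496: {"E": 0.4, "T": 0.4, "G": 0.2},
        576: {"G": 0.7, "A": 0.3},
        603: {"A": 0.5, "G": 0.5},
    },
}

DEFAULT_CLADE_SIZES = {"NifI": 25, "NifII": 25, "Divergent": 10}


def make_extant_fixture(
    seed: int,
    clade_profiles: dict | None = None,
    clade_sizes: dict | None = None,
    length: int = 750,
) -> tuple[Alignment, dict[str, str]]:
    """Small extant-diversity alignment with clade-structured variation.

    Panel columns other than the five variable ones carry the panel's
    conserved residue; non-panel columns carry a fixed cycling
    background.  Returns the alignment and an id→clade map.
    """
    rng = np.random.default_rng(seed)
    profiles = clade_profiles or DEFAULT_CLADE_PROFILES
    sizes = clade_sizes or DEFAULT_CLADE_SIZES
    panel = load_panel()
    if length < max(panel.columns):
        raise ValueError("alignment length shorter than the panel")
    background = list((AA_LETTERS * (length // 20 + 1))[:length])
    for entry in panel.entries:
        background[entry.column - 1] = entry.conserved_residue

    ids, rows, clade_map = [], [], {}
    for clade, size in sizes.items():
        profile = profiles[clade]
        for i in range(size):
            sid = f"{clade}_{i + 1:02d}"
            row = background.copy()
            for col, freqs in profile.items():
                residues = sorted(freqs)
                weights = np.array([freqs[r] for r in residues], dtype=float)
                weights /= weights.sum()
                row[col - 1] = residues[rng.choice(len(residues), p=weights)]
            ids.append(sid)
            rows.append("".join(row))
            clade_map[sid] = clade
    return Alignment(ids=ids, rows=rows), clade_map
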