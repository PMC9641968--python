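"""Felsenstein pruning likelihood and marginal ancestral reconstruction.

The engine computes, for a rooted tree, alignment and reversible model,
per-site log-likelihoods

    log L(site) = log sum_k w_k sum_x pi_x L_k,root(x)

by postorder accumulation of conditional (partial) likelihood vectors,
with per-node log-scaling against underflow.  Marginal posteriors at an
internal node are obtained by re-rooting the tree at that node — valid
under reversibility — and reading off

    P(node = x | data) = sum_k w_k pi_x L_k,node(x) / normalizer,

where the rate categories are mixed by their site-specific posterior
weight.  Gaps and 'X' at leaves are treated as missing data (an all-ones
partial vector).
"""

from __future__ import annotations

import numpy as np

from .io_phylo import (
    AA_INDEX,
    Alignment,
    Phylogeny,
    StateTable,
    TreeError,
    mrca,
    root_on_outgroup,
)
from .substitution_models import SubstitutionModel, build_rate_matrix, transition_probs

__all__ = [
    "site_log_likelihood",
    "log_likelihoods",
    "marginal_asr",
    "run_asr_pipeline",
]


def _leaf_partials(aln: Alignment, label: str, sites: np.ndarray) -> np.ndarray:
    """Indicator partial vectors for a leaf, shape (n_sites, 20)."""
    try:
        row = aln.row(label)
    except KeyError:
        raise TreeError(f"leaf {label!r} has no alignment row") from None
    out = np.zeros((len(sites), 20))
    for i, site in enumerate(sites):
        ch = row[site - 1]
        if ch in ("-", "X"):
            out[i, :] = 1.0
        else:
            out[i, AA_INDEX[ch]] = 1.0
    return out


def _postorder_partials(tree, aln: Alignment, model: SubstitutionModel, sites: np.ndarray):
    """Partial likelihoods at the seed node.

    Returns ``(L, logscale)`` with ``L`` of shape (n_cat, n_sites, 20) and
    ``logscale`` of shape (n_sites,) holding the accumulated log scaling
    factors (shared across categories so mixture weights stay valid).
    """
    rm = build_rate_matrix(model)
    ncat = model.n_categories
    nsites = len(sites)
    pmat_cache: dict = {}

    def edge_pmats(length: float) -> np.ndarray:
        key = round(float(length), 15)
        if key not in pmat_cache:
            pmat_cache[key] = np.stack(
                [transition_probs(rm, length, r) for r in model.rates]
            )
        return pmat_cache[key]

    partials: dict = {}
    logscale: dict = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            leaf = _leaf_partials(aln, node.taxon.label, sites)
            partials[node] = np.broadcast_to(leaf, (ncat, nsites, 20)).copy()
            logscale[node] = np.zeros(nsites)
            continue
        L = np.ones((ncat, nsites, 20))
        ls = np.zeros(nsites)
        for child in children:
            t = child.edge.length if child.edge.length is not None else 0.0
            P = edge_pmats(t)  # (ncat, 20, 20)
            # sum_y P[x, y] * L_child[y]
            L *= np.einsum("kxy,ksy->ksx", P, partials.pop(child))
            ls += logscale.pop(child)
        m = L.max(axis=(0, 2))  # per-site scale across categories and states
        if np.any(m <= 0):
            bad = sites[np.where(m <= 0)[0][0]]
            raise ValueError(f"zero likelihood at site {bad}")
        L /= m[None, :, None]
        partials[node] = L
        logscale[node] = ls + np.log(m)
    root = tree.seed_node
    return partials[root], logscale[root]


def log_likelihoods(
    phy: Phylogeny, aln: Alignment, model: SubstitutionModel, sites=None
) -> np.ndarray:
    """Per-site pruning log-likelihoods (1-based ``sites``; default all)."""
    if sites is None:
        sites = np.arange(1, aln.length + 1)
    sites = np.asarray(sites, dtype=int)
    L, ls = _postorder_partials(phy.tree, aln, model, sites)
    per_cat = L @ model.pi  # (ncat, nsites)
    tot = model.weights @ per_cat
    return np.log(tot) + ls


def site_log_likelihood(
    phy: Phylogeny, aln: Alignment, model: SubstitutionModel, site: int
) -> float:
    """Pruning log-likelihood of one 1-based alignment column."""
    return float(log_likelihoods(phy, aln, model, sites=[site])[0])


def _matching_node(phy: Phylogeny, node):
    """Locate the clone's node with the same subtended leaf set."""
    want = frozenset(lf.taxon.label for lf in node.leaf_iter())
    for cand in phy.tree.preorder_node_iter():
        if frozenset(lf.taxon.label for lf in cand.leaf_iter()) == want:
            return cand
    raise TreeError("node not found in cloned tree")


def marginal_asr(
    phy: Phylogeny,
    aln: Alignment,
    model: SubstitutionModel,
    node,
    sites=None,
    node_id: str = "Anc",
) -> StateTable:
    """Marginal posterior state distributions at an internal node.

    The posterior is computed with the tree re-rooted at ``node``; under a
    reversible model the result does not depend on the original root
    placement.  Returns a :class:`StateTable` keyed by ``node_id``.
    """
    if node.is_leaf():
        raise TreeError("marginal reconstruction target must be an internal node")
    if sites is None:
        sites = np.arange(1, aln.length + 1)
    sites = np.asarray(sites, dtype=int)

    work = phy.clone()
    target = _matching_node(work, node)
    if target is not work.tree.seed_node:
        work.tree.reroot_at_node(target, update_bipartitions=False)
        work.tree.seed_node.edge.length = None

    L, _ = _postorder_partials(work.tree, aln, model, sites)
    mixed = np.einsum("k,ksx->sx", model.weights, L) * model.pi[None, :]
    mixed /= mixed.sum(axis=1, keepdims=True)

    table = StateTable()
    for i, site in enumerate(sites):
        table.set(node_id, int(site), mixed[i])
    return table


def run_asr_pipeline(
    aln: Alignment,
    tree: Phylogeny,
    model: SubstitutionModel,
    outgroup,
    ingroup_taxa,
    node_id: str = "Anc",
    sites=None,
    logger=None,
) -> StateTable:
    """Root on the outgroup, find the ingroup MRCA, and reconstruct there.

    Returns the marginal state table at the MRCA for every alignment
    column (or the 1-based ``sites`` requested).
    """
    rooted = root_on_outgroup(tree, outgroup)
    node = mrca(rooted, ingroup_taxa)
    if node.is_leaf():
        raise TreeError("ingroup MRCA is a single leaf; nothing to reconstruct")
    table = marginal_asr(rooted, aln, model, node, sites=sites, node_id=node_id)
    if logger is not None:
        logger.info(
            "ASR model=%s categories=%d node=%s sites=%d",
            model.name,
            model.n_categories,
            node_id,
            len(table.sites(node_id)),
        )
        for site in table.sites(node_id):
            probs = table.residue_probs(node_id, site)
            top = max(probs, key=probs.get)
            logger.debug("site %d top state %s p=%.5f", site, top, probs[top])
    return table
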