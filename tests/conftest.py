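import itertools

import numpy as np
import pytest

import ancsite as ac
from ancsite.io_phylo import AA_INDEX


@pytest.fixture(scope="session")
def lg_uniform():
    return ac.load_model("LG", "uniform")


@pytest.fixture(scope="session")
def lg_gamma4():
    return ac.load_model("LG", {"gamma": {"alpha": 1.0, "k": 4}})


@pytest.fixture(scope="session")
def anc_fixture():
    """Packaged nitrogenase-ancestor fixture: (state table, 24-site panel)."""
    return ac.make_ancestor_fixture()


def brute_force_site(tree, aln, model, site):
    """Independent likelihood/posterior oracle by explicit enumeration.

    Sums the joint probability of every assignment of states to the
    internal nodes (per rate category, mixed by category weight).
    Returns (site_likelihood, {node: posterior_vector}) for all internal
    nodes.  Exponential in the number of internal nodes; use on trees
    with at most 5 leaves.
    """
    internals = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    index = {n: i for i, n in enumerate(internals)}
    root = tree.tree.seed_node
    total = 0.0
    post = {n: np.zeros(20) for n in internals}
    rm = ac.build_rate_matrix(model)
    for w, r in zip(model.weights, model.rates):
        pmats = {
            n: ac.transition_probs(rm, n.edge.length or 0.0, r)
            for n in tree.tree.preorder_node_iter()
            if n is not root
        }
        # fold each internal node's leaf children into a message over its state
        leafmsg = []
        for n in internals:
            msg = np.ones(20)
            for child in n.child_nodes():
                if child.is_leaf():
                    ch = aln.row(child.taxon.label)[site - 1]
                    if ch not in ("-", "X"):  # missing data marginalizes to 1
                        msg = msg * pmats[child][:, AA_INDEX[ch]]
            leafmsg.append(msg)
        internal_edges = [
            (index[n.parent_node], index[n]) for n in internals if n is not root
        ]
        for assignment in itertools.product(range(20), repeat=len(internals)):
            pr = w * model.pi[assignment[index[root]]]
            for pi_idx, ci_idx in internal_edges:
                pr *= pmats[internals[ci_idx]][assignment[pi_idx], assignment[ci_idx]]
            for i, msg in enumerate(leafmsg):
                pr *= msg[assignment[i]]
            total += pr
            for i, n in enumerate(internals):
                post[n][assignment[i]] += pr
    return total, {n: v / total for n, v in post.items()}
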