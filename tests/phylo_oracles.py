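"""Independent oracles for the phylogenetics tests.

Everything here is deliberately naive: exhaustive enumeration instead of
pruning, explicit path sums instead of matrix reductions.  The oracles never
call the code paths they check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from lineakit.phylo import T92Model, T92Params

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_loglik(tree: dendropy.Tree, ids, seqs, params: T92Params) -> float:
    """Site likelihood by explicit summation over all internal-state combos.

    Missing leaf characters ('-'/'N') are summed over all four states, which
    is the definition of "partial likelihood one in every state".
    """
    model = T92Model(params)
    pmats = {}
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        if node.parent_node is not None:
            t = node.edge.length if node.edge.length is not None else 0.0
            pmats[id(node)] = model.transition_matrix(t)
    leaf_row = {name: i for i, name in enumerate(ids)}
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    n_sites = len(seqs[0])
    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        leaf_state_options = []
        for leaf in leaves:
            ch = seqs[leaf_row[leaf.taxon.label]][site].upper()
            leaf_state_options.append([_CODE[ch]] if ch in _CODE else [0, 1, 2, 3])
        for internal_states in itertools.product(range(4), repeat=len(internals)):
            assigned = {id(n): s for n, s in zip(internals, internal_states)}
            for leaf_states in itertools.product(*leaf_state_options):
                for leaf, s in zip(leaves, leaf_states):
                    assigned[id(leaf)] = s
                p = model.pi[assigned[id(tree.seed_node)]]
                for node in nodes:
                    if node.parent_node is not None:
                        p *= pmats[id(node)][
                            assigned[id(node.parent_node)], assigned[id(node)]
                        ]
                site_lik += p
        total += np.log(site_lik)
    return float(total)


def all_unrooted_topologies(taxa: list[str]) -> list[dendropy.Tree]:
    """Every unrooted binary topology on the given taxa (3 for n=4, 15 for n=5).

    Built by sequential insertion of each taxon into every edge of every
    partial topology; trees carry no branch lengths.
    """
    assert len(taxa) >= 3

    def copy_tree(tree: dendropy.Tree) -> dendropy.Tree:
        return tree.clone(depth=1)

    tns = dendropy.TaxonNamespace(taxa)
    root = dendropy.Node()
    for t in taxa[:3]:
        node = dendropy.Node(taxon=tns.get_taxon(t))
        root.add_child(node)
    base = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    base.is_rooted = False
    trees = [base]
    for taxon in taxa[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
            for k in range(len(edges)):
                new = copy_tree(tree)
                target = [
                    n for n in new.preorder_node_iter() if n.parent_node is not None
                ][k]
                parent = target.parent_node
                mid = dendropy.Node()
                parent.remove_child(target)
                parent.add_child(mid)
                mid.add_child(target)
                leaf = dendropy.Node(taxon=new.taxon_namespace.get_taxon(taxon))
                mid.add_child(leaf)
                nxt.append(new)
        trees = nxt
    return trees


def assign_random_branch_lengths(
    tree: dendropy.Tree, rng: np.random.Generator, low: float = 0.02, high: float = 0.4
) -> dendropy.Tree:
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(low, high))
    return tree


def path_length_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix by explicit root-path arithmetic."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = {}
        node = leaf
        total = 0.0
        while node.parent_node is not None:
            total += node.edge.length or 0.0
            node = node.parent_node
            path[id(node)] = total
        paths[leaf.taxon.label] = (path, total)
    n = len(taxa)
    out = np.zeros((n, n))
    ancestors = {
        name: paths[name][0] for name in taxa
    }
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            b = taxa[j]
            best = np.inf
            for anc, da in ancestors[a].items():
                if anc in ancestors[b]:
                    best = min(best, da + ancestors[b][anc])
            out[i, j] = out[j, i] = best
    return out


def random_binary_tree(
    taxa: list[str], rng: np.random.Generator
) -> dendropy.Tree:
    """A random unrooted binary topology with random branch lengths."""
    topologies = all_unrooted_topologies(taxa)
    tree = topologies[int(rng.integers(0, len(topologies)))]
    return assign_random_branch_lengths(tree, rng)
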