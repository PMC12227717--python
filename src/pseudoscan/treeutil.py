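"""Rooted-tree helpers shared across the pipeline (thin layer over dendropy).

Branches are identified by the label of the node *below* the branch (its
head): for tips this is the taxon label, for internal nodes an explicit
newick label or a deterministic auto-assigned ``n<k>`` in preorder.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy


def load_tree(source) -> dendropy.Tree:
    """Load a rooted tree from a newick string, a path, or pass through a Tree.

    Internal nodes without labels get deterministic preorder labels so every
    branch is addressable.
    """
    if isinstance(source, dendropy.Tree):
        tree = source
    else:
        text = str(source)
        if text.lstrip().startswith("("):
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                path=text, schema="newick", preserve_underscores=True
            )
    tree.is_rooted = True
    label_nodes(tree)
    return tree


def label_nodes(tree: dendropy.Tree) -> None:
    """Ensure every node carries a unique label (tips: taxon label)."""
    taken = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            if nd.taxon is None:
                raise ValueError("leaf without taxon in tree")
            nd.label = nd.taxon.label
            taken.add(nd.label)
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if not nd.label or nd.label in taken:
            while f"n{k}" in taken:
                k += 1
            nd.label = f"n{k}"
        taken.add(nd.label)


def branch_id(node: dendropy.Node) -> str:
    return node.label


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def leaves_under(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for nd in tree.preorder_node_iter():
        if nd.label == label:
            return nd
    raise KeyError(f"no node labelled {label!r} in tree")


def mrca(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Node:
    labels = list(labels)
    missing = set(labels) - set(tip_labels(tree))
    if missing:
        raise KeyError(f"species absent from tree: {sorted(missing)}")
    taxa = [tree.taxon_namespace.get_taxon(lb) for lb in labels]
    node = tree.mrca(taxa=taxa)
    if node is None:
        raise ValueError("could not resolve MRCA")
    return node


def branch_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    """All nodes that head a branch (everything except the seed node), preorder."""
    root = tree.seed_node
    return [nd for nd in tree.preorder_node_iter() if nd is not root]


def branch_of_mrca(tree: dendropy.Tree, labels: Iterable[str]) -> str:
    """Branch id of the stem above the MRCA of the given tips."""
    return branch_id(mrca(tree, labels))
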