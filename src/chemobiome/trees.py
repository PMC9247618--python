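"""Newick handling shared by the simulator and UniFrac.

dendropy does the parsing/writing; this module only flattens a tree into the
edge x leaf incidence structure that per-branch UniFrac classification needs,
and grows random bifurcating trees for simulated communities.
"""

from __future__ import annotations

import numpy as np
import dendropy

__all__ = ["parse_newick", "tree_edge_matrix", "random_bifurcating_newick"]


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string (quoted labels and branch lengths supported)."""
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def tree_edge_matrix(newick: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Flatten a newick tree into (edge x leaf incidence, edge lengths, leaf names).

    One row per non-root branch; entry (e, l) is True iff leaf l lies below
    branch e.  Branches with missing lengths count as length 0.
    """
    tree = parse_newick(newick)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in tree")
    leaf_idx = {name: i for i, name in enumerate(leaves)}
    rows, lengths = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        mask = np.zeros(len(leaves), dtype=bool)
        for lf in node.leaf_iter():
            mask[leaf_idx[lf.taxon.label]] = True
        rows.append(mask)
        lengths.append(node.edge.length or 0.0)
    return np.array(rows), np.array(lengths, dtype=float), leaves


def random_bifurcating_newick(leaf_ids, seed: int = 0) -> str:
    """Random bifurcating tree over ``leaf_ids`` with positive branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees; branch lengths
    are exponential with a small positive floor.  Deterministic under seed.
    """
    ids = list(leaf_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 leaf ids")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate leaf ids")
    rng = np.random.default_rng(seed)

    def blen() -> str:
        return f"{rng.exponential(0.5) + 0.01:.6f}"

    nodes = [f"{i}:{blen()}" for i in ids]
    while len(nodes) > 2:
        a, b = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(b)
        left = nodes.pop(a)
        nodes.append(f"({left},{right}):{blen()}")
    return f"({nodes[0]},{nodes[1]});"
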