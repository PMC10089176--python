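"""Rooted time trees for discrete-geographic inference.

A :class:`Tree` is a fixed, rooted, time-calibrated phylogeny: topology plus
branch durations in the tree's own time units.  The tree is *data*, never a
parameter — inference of geographic history conditions on it.  The only
derived quantity the dispersal model cares about beyond topology is the tree
length ``T`` (sum of all branch durations), which calibrates the default
prior on the average dispersal rate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Tree", "read_newick_tree", "write_newick"]


@dataclass
class Tree:
    """Rooted tree stored as parent-pointer arrays in postorder-friendly form.

    Parameters
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; the root has -1.
    branch_length : ndarray of float
        Duration of the branch subtending each node (0.0 for the root).
    tip_labels : dict
        Map node id -> taxon label, for tip nodes only.
    """

    parent: np.ndarray
    branch_length: np.ndarray
    tip_labels: dict[int, str]
    name: str | None = None
    _children: list[list[int]] = field(init=False, repr=False)
    _postorder: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_length = np.asarray(self.branch_length, dtype=np.float64)
        n = self.parent.size
        if self.branch_length.size != n:
            raise ValueError("parent and branch_length must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any(self.branch_length < 0):
            raise ValueError("negative branch duration")
        labels = list(self.tip_labels.values())
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        self._children = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                self._children[p].append(i)
        for i, ch in enumerate(self._children):
            if not ch and i not in self.tip_labels:
                raise ValueError(f"leaf node {i} has no tip label")
        # iterative postorder (children before parents)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self._children[v])
        self._postorder = np.array(order[::-1], dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tips(self) -> list[int]:
        return sorted(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self._children[i]]

    def children(self, node: int) -> list[int]:
        return self._children[node]

    @property
    def postorder(self) -> np.ndarray:
        """Node ids, every child before its parent; root last."""
        return self._postorder

    @property
    def preorder(self) -> np.ndarray:
        return self._postorder[::-1]

    @property
    def tree_length(self) -> float:
        """T: the sum of the durations of all branches."""
        return float(self.branch_length.sum())

    # ------------------------------------------------------------------
    def validate_for_inference(self) -> None:
        """Raise if the tree cannot support a dispersal analysis (T == 0)."""
        if self.tree_length <= 0.0:
            raise ValueError("tree length T must be > 0 for inference")


def read_newick_tree(text: str, name: str | None = None) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Branch lengths are required on every non-root branch; a missing length
    or duplicate tip label is an error.  ``T = 0`` trees parse fine but are
    rejected by :meth:`Tree.validate_for_inference`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse failure: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    blen = np.zeros(len(nodes), dtype=np.float64)
    tip_labels: dict[int, str] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError("missing branch length on a non-root branch")
            blen[i] = float(nd.edge.length)
        elif nd.edge.length:
            blen[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise ValueError("unlabeled tip")
            tip_labels[i] = nd.taxon.label
    return Tree(parent=parent, branch_length=blen, tip_labels=tip_labels, name=name)


def read_nexus_tree(text: str) -> Tree:
    """Read the first tree from a NEXUS TREES block."""
    dtree = dendropy.Tree.get(data=text, schema="nexus", suppress_internal_node_taxa=True)
    out = io.StringIO()
    out.write(dtree.as_string(schema="newick", suppress_rooting=True))
    return read_newick_tree(out.getvalue())


def write_newick(tree: Tree, node_comments: dict[int, str] | None = None) -> str:
    """Serialize to newick; ``node_comments[i]`` is inserted as ``[&...]``
    after node ``i`` (BEAST-style annotations)."""

    def fmt(node: int) -> str:
        comment = node_comments.get(node, "") if node_comments else ""
        if not tree.children(node):
            label = tree.tip_labels[node]
            return f"{label}{comment}:{tree.branch_length[node]:.12g}"
        inner = ",".join(fmt(c) for c in tree.children(node))
        if tree.parent[node] < 0:
            return f"({inner}){comment}"
        return f"({inner}){comment}:{tree.branch_length[node]:.12g}"

    return fmt(tree.root) + ";"
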