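"""Rooted ultrametric trees: Newick I/O, heights, and a UPGMA fallback.

Node heights are measured as time before present: tips sit at height 0 and
every parent is at least as high as its children.  Trees are stored as plain
linked nodes; parsing and serialization go through dendropy.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError, UltrametricityError
from .seqdist import DistanceMatrix


class TreeNode:
    __slots__ = ("name", "height", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        height: float = 0.0,
        children: Optional[list["TreeNode"]] = None,
    ):
        self.name = name
        self.height = height
        self.children: list[TreeNode] = children or []
        self.parent: Optional[TreeNode] = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r}, h={self.height:.4g})"


class UltrametricTree:
    """A rooted binary ultrametric tree with tips at height 0."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            # reversed keeps left-to-right child order in the output
            stack.extend(reversed(node.children))
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def internal_heights(self) -> list[float]:
        """Heights of internal nodes, descending (root first)."""
        return sorted((n.height for n in self.internal_nodes()), reverse=True)

    @property
    def root_height(self) -> float:
        return self.root.height

    def leaf_names_below(self, node: TreeNode) -> frozenset[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def rescale(self, factor: float) -> "UltrametricTree":
        """Multiply all heights by ``factor`` (time-unit change)."""
        for n in self.preorder():
            n.height *= factor
        return self

    # -- Newick I/O --------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.parent is None:
                return body
            bl = node.parent.height - node.height
            return f"{body}:{bl:.12g}"

        return fmt(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree, rel_tol: float = 1e-6) -> UltrametricTree:
    seed = dtree.seed_node

    # depth of every node from the root, validating branch lengths
    depth: dict = {seed: 0.0}
    for node in dtree.preorder_node_iter():
        if node is seed:
            continue
        bl = node.edge.length
        if bl is None:
            raise InputError("Newick tree is missing branch lengths")
        if bl < 0:
            raise InputError(f"negative branch length {bl} in Newick tree")
        depth[node] = depth[node.parent_node] + bl

    leaves = [n for n in dtree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InputError("tree must have at least 2 tips")
    names = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(n is None for n in names):
        raise InputError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        raise InputError("tree has duplicate tip labels")

    root_height = max(depth[lf] for lf in leaves)
    tol = rel_tol * root_height if root_height > 0 else rel_tol
    hi = max(leaves, key=lambda lf: depth[lf])
    lo = min(leaves, key=lambda lf: depth[lf])
    if depth[hi] - depth[lo] > tol:
        raise UltrametricityError(
            f"tree is not ultrametric: tips {hi.taxon.label!r} and "
            f"{lo.taxon.label!r} differ in root-to-tip distance "
            f"({depth[hi]:.6g} vs {depth[lo]:.6g})"
        )

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(name=dnode.taxon.label, height=0.0)
        kids = [convert(c) for c in dnode.child_nodes()]
        if len(kids) > 2:
            warnings.warn(
                "polytomy resolved arbitrarily with zero-length branches",
                stacklevel=2,
            )
            h = root_height - depth[dnode]
            while len(kids) > 2:
                merged = TreeNode(height=h, children=[kids.pop(0), kids.pop(0)])
                kids.insert(0, merged)
        node = TreeNode(height=root_height - depth[dnode])
        for k in kids:
            node.add_child(k)
        return node

    tree = UltrametricTree(convert(seed))
    # snap near-zero tip heights introduced by rounding
    for t in tree.tips():
        t.height = 0.0
    return tree


def read_newick(source: str | Path, rel_tol: float = 1e-6) -> UltrametricTree:
    """Read an ultrametric tree from a Newick file or literal string."""
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        path = Path(source)
        if not path.exists():
            raise InputError(f"Newick file not found: {path}")
        data = path.read_text()
    else:
        data = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise InputError(f"could not parse Newick input: {exc}") from exc
    return _from_dendropy(dtree, rel_tol=rel_tol)


def write_newick(tree: UltrametricTree, path: str | Path) -> None:
    tree.write_newick(path)


def upgma_tree(m: DistanceMatrix) -> UltrametricTree:
    """UPGMA (average-linkage) tree; node height = merge distance / 2.

    A fallback for when no time-calibrated genealogy is available; output is
    always ultrametric by construction.
    """
    if m.has_saturated():
        pairs = [
            (m.ids[i], m.ids[j])
            for i in range(m.n)
            for j in range(i + 1, m.n)
            if m.saturated[i, j]
        ]
        raise InputError(
            f"distance matrix has saturated pairs {pairs[:3]}...; exclude "
            "those sequences before building a UPGMA tree"
        )
    if m.n < 2:
        raise InputError("need at least 2 sequences for UPGMA")
    if m.n == 2:
        h = m.d[0, 1] / 2.0
        root = TreeNode(
            height=h,
            children=[TreeNode(m.ids[0], 0.0), TreeNode(m.ids[1], 0.0)],
        )
        return UltrametricTree(root)
    condensed = squareform(np.asarray(m.d, dtype=float), checks=False)
    z = linkage(condensed, method="average")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=m.ids[i], height=0.0) for i in range(m.n)
    }
    for k, (a, b, dist, _count) in enumerate(z):
        node = TreeNode(
            height=dist / 2.0, children=[nodes[int(a)], nodes[int(b)]]
        )
        nodes[m.n + k] = node
    root = nodes[m.n + len(z) - 1]
    # average linkage can produce tiny non-monotone steps on near-degenerate
    # input; enforce parent >= child exactly
    tree = UltrametricTree(root)
    for n in tree.preorder():
        for c in n.children:
            if c.height > n.height:
                c.height = n.height
    return tree


def tree_from_groups_check(tree: UltrametricTree) -> None:
    """Validate the ultrametric-tree invariants; raise on violation."""
    for n in tree.preorder():
        for c in n.children:
            if c.height > n.height + 1e-12:
                raise UltrametricityError(
                    f"child height {c.height} exceeds parent height {n.height}"
                )
    tol = 1e-6 * max(tree.root_height, 1e-12)
    for t in tree.tips():
        if abs(t.height) > tol:
            raise UltrametricityError(f"tip {t.name!r} not at height 0")
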