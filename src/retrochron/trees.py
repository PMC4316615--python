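"""Rooted trees shared by the simulator, marker mapping and reconciliation.

A deliberately small tree structure: named nodes, parent/child links and
optional non-negative branch lengths. Newick text is parsed and written
through dendropy so the dialect handling (quoting, comments, internal node
labels) is not reimplemented here; the in-memory form is this module's own
because reconciliation needs cheap ancestor tests and stable node identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


class NewickError(ValueError):
    """Raised when Newick text cannot be parsed."""


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


class Tree:
    """A single-rooted tree with unique leaf names."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [lf.name for lf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be named")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")

    # -- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- lookup ----------------------------------------------------------
    def find(self, name: str) -> Optional[TreeNode]:
        """First node (preorder) whose name equals ``name``; None if absent."""
        for node in self.preorder():
            if node.name == name:
                return node
        return None

    def depth(self, node: TreeNode) -> int:
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def is_ancestor(self, anc: TreeNode, node: TreeNode, strict: bool = False) -> bool:
        """True if ``anc`` lies on the root path of ``node`` (inclusive unless strict)."""
        if anc is node:
            return not strict
        cur = node.parent
        while cur is not None:
            if cur is anc:
                return True
            cur = cur.parent
        return False

    def mrca(self, nodes: list[TreeNode]) -> TreeNode:
        if not nodes:
            raise ValueError("mrca of empty node set")
        paths = []
        for n in nodes:
            path = []
            cur = n
            while cur is not None:
                path.append(cur)
                cur = cur.parent
            paths.append(list(reversed(path)))
        anc = None
        for level in zip(*paths):
            if all(x is level[0] for x in level):
                anc = level[0]
            else:
                break
        assert anc is not None  # all paths share the root
        return anc

    def clade_leaf_names(self, node: TreeNode) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def copy(self) -> "Tree":
        return read_newick(write_newick(self))


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    name = None
    if dnode.taxon is not None:
        name = dnode.taxon.label
    elif dnode.label is not None:
        name = dnode.label
    node = TreeNode(name=name, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def read_newick(text: str) -> Tree:
    """Parse one Newick tree, preserving internal node names and branch lengths."""
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError(
            f"missing terminating ';' at offset {len(stripped)}"
        )
    if stripped.count("(") != stripped.count(")"):
        off = max(stripped.rfind("("), stripped.rfind(")"))
        raise NewickError(f"unbalanced parentheses near offset {off}")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse error: {exc}") from exc
    return Tree(_from_dendropy(dtree.seed_node))


def _to_newick(node: TreeNode) -> str:
    label = node.name or ""
    blen = "" if node.length is None else f":{node.length:g}"
    if node.is_leaf:
        return f"{label}{blen}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}){label}{blen}"


def write_newick(tree: Tree) -> str:
    return _to_newick(tree.root) + ";"
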