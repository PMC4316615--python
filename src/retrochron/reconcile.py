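"""TE-tree / host-tree reconciliation and retention mapping.

Under vertical transmission, a TE subfamily tree evolves inside the host
phylogeny like a gene tree inside a species tree. LCA reconciliation maps
every TE-tree node to the host-tree MRCA of its descendants' hosts; a node
mapping to the same host node as one of its children is a duplication (two
TE lineages co-existing in one ancestral genome), otherwise a speciation.
The minimum number of TE lineages present in a focal host ancestor is then
the number of TE-tree edges crossing into that ancestor from above plus the
duplications mapped exactly onto it. Dollo parsimony (single gain, unlimited
losses) places lineage losses on the host tree from extant presence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .trees import Tree, TreeNode


@dataclass
class LabeledTETree:
    tree: Tree
    host_labels: dict[str, str]           # TE leaf name -> host tree node name
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [lf for lf in self.tree.leaf_names() if lf not in self.host_labels]
        if missing:
            raise ValueError(f"TE leaves without host labels: {missing}")


@dataclass
class Reconciliation:
    mapping: dict[int, TreeNode]          # id(te node) -> host node
    events: dict[int, str]                # id(te node) -> 'duplication'|'speciation'|'leaf'

    def host_of(self, node: TreeNode) -> TreeNode:
        return self.mapping[id(node)]

    def event_of(self, node: TreeNode) -> str:
        return self.events[id(node)]


def lca_map(te: LabeledTETree, host: Tree) -> Reconciliation:
    """LCA reconciliation with duplication/speciation labelling."""
    host_nodes: dict[str, TreeNode] = {}
    for node in host.preorder():
        if node.name:
            host_nodes.setdefault(node.name, node)
    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    for node in te.tree.postorder():
        if node.is_leaf:
            label = te.host_labels[node.name]
            if label not in host_nodes:
                raise ValueError(
                    f"leaf {node.name!r}: host label {label!r} not in host tree"
                )
            mapping[id(node)] = host_nodes[label]
            events[id(node)] = "leaf"
        else:
            children_maps = [mapping[id(c)] for c in node.children]
            m = host.mrca(children_maps)
            mapping[id(node)] = m
            events[id(node)] = (
                "duplication" if any(cm is m for cm in children_maps) else "speciation"
            )
    return Reconciliation(mapping=mapping, events=events)


@dataclass
class LineageCount:
    count: int
    crossing_edges: list[str]       # labels of child nodes of counted edges
    duplication_births: list[str]   # labels of duplication nodes at the focal node


def _node_label(tree: Tree, node: TreeNode) -> str:
    return node.name or "+".join(sorted(tree.clade_leaf_names(node)))


def min_ancestral_lineages(
    te: LabeledTETree, host: Tree, focal: str
) -> LineageCount:
    """Minimum TE lineages present in the named host ancestor.

    A virtual origin edge above the TE root (mapped to the host root) lets
    outgroup-rooted TE trees contribute their crossing edge into the focal
    clade. Edges whose top maps strictly above the focal node and whose
    bottom maps at or below it are crossings; duplications mapped exactly to
    the focal node are additional within-ancestor lineage births (speciation
    nodes there are a single copy co-diverging with its hosts).
    """
    focal_node = host.find(focal)
    if focal_node is None:
        raise ValueError(f"host node {focal!r} not found")
    rec = lca_map(te, host)
    crossings: list[str] = []
    dups: list[str] = []

    def below(n: TreeNode) -> bool:
        return host.is_ancestor(focal_node, n)

    def strictly_above(n: TreeNode) -> bool:
        return host.is_ancestor(n, focal_node, strict=True)

    # virtual origin edge: host root -> map(te root)
    te_root = te.tree.root
    if strictly_above(host.root) or host.root is not focal_node:
        if below(rec.host_of(te_root)) and host.is_ancestor(
            host.root, focal_node, strict=True
        ):
            crossings.append(_node_label(te.tree, te_root))
    else:
        # focal is the host root: the origin edge always enters it
        crossings.append(_node_label(te.tree, te_root))
    for node in te.tree.preorder():
        for child in node.children:
            if strictly_above(rec.host_of(node)) and below(rec.host_of(child)):
                crossings.append(_node_label(te.tree, child))
        if rec.host_of(node) is focal_node and rec.event_of(node) == "duplication":
            dups.append(_node_label(te.tree, node))
    import warnings

    count = len(crossings) + len(dups)
    if count == 0:
        warnings.warn(f"focal node {focal!r} lies on no mapped path", stacklevel=2)
    return LineageCount(
        count=count, crossing_edges=crossings, duplication_births=dups
    )


# ---------------------------------------------------------------------------
# Dollo retention
# ---------------------------------------------------------------------------

@dataclass
class DolloResult:
    # group -> names of host nodes whose stem branch retains the group
    retained: dict[str, set[str]]
    # group -> host nodes on whose stem the loss is placed
    losses: dict[str, list[str]]


def dollo_retention(
    host: Tree,
    presence: dict[str, set[str]],
    origin: str,
) -> DolloResult:
    """Dollo parsimony retention of each TE group on the host tree.

    Each group is gained once at ``origin``, retained on every branch from
    the origin to each extant taxon carrying it, and lost once on the stem
    of each maximal presence-free clade. The returned loss placement is the
    unique minimum-loss solution under single-gain parsimony.
    """
    import warnings

    origin_node = host.find(origin)
    if origin_node is None:
        raise ValueError(f"origin node {origin!r} not found")
    origin_leaves = host.clade_leaf_names(origin_node)
    retained: dict[str, set[str]] = {}
    losses: dict[str, list[str]] = {}
    for group, taxa in presence.items():
        if not taxa:
            warnings.warn(f"group {group!r} present nowhere; lost at origin",
                          stacklevel=2)
            retained[group] = set()
            losses[group] = [origin]
            continue
        outside = set(taxa) - set(origin_leaves)
        if outside:
            raise ValueError(
                f"group {group!r}: taxa outside the origin clade: {sorted(outside)}"
            )
        keep: set[str] = set()
        loss: list[str] = []

        def visit(node: TreeNode) -> bool:
            """Returns True if the subtree contains any presence taxon."""
            if node.is_leaf:
                has = node.name in taxa
            else:
                child_has = [visit(c) for c in node.children]
                has = any(child_has)
                if has:
                    for c, ch in zip(node.children, child_has):
                        if not ch:
                            loss.append(_node_label(host, c))
            if has and node is not origin_node:
                keep.add(_node_label(host, node))
            return has

        has_any = visit(origin_node)
        if not has_any:
            loss.append(origin)
        retained[group] = keep
        losses[group] = loss
    return DolloResult(retained=retained, losses=losses)


def count_dollo_losses(result: DolloResult, group: str) -> int:
    return len(result.losses[group])
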