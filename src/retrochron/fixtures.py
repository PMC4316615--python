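"""Packaged worked-example fixtures.

The CR1 subfamily tree shipped here is a synthetic class-level rendering of
the published amniote CR1 phylogeny: leaves stand for subfamily clades
collapsed to one tip per (group, host class), host labels are amniote
classes, and the inter-group backbone interleaves the mammal-bearing groups
(B, C, G) among the reptile-restricted ones (A, D, E, F) so that every
inter-group node maps to the amniote ancestor. The minimum-lineage count at
Amniota depends on exactly this interleaving — with the mammal-bearing
groups clustered together the count would drop, and with a mammal/lepidosaur
cherry inside group C it would rise; the shipped arrangement is the one the
published seven-lineage inference implies.
"""

from __future__ import annotations

from importlib import resources

from .reconcile import LabeledTETree
from .trees import Tree, read_newick


def _read(name: str) -> str:
    return (resources.files("retrochron") / "data" / name).read_text()


def amniote_host_tree() -> Tree:
    """Consensus amniote class-level host phylogeny, rooted at Tetrapoda."""
    return read_newick(_read("amniote_hosts.nwk"))


def cr1_te_tree() -> LabeledTETree:
    """Synthetic class-level CR1 subfamily tree with host and group labels."""
    tree = read_newick(_read("cr1_te_tree_synthetic.nwk"))
    host_labels: dict[str, str] = {}
    group_labels: dict[str, str] = {}
    for line in _read("cr1_host_labels_synthetic.tsv").splitlines():
        if not line or line.startswith("#"):
            continue
        leaf, host, group = line.split("\t")
        host_labels[leaf] = host
        group_labels[leaf] = group
    return LabeledTETree(
        tree=tree, host_labels=host_labels, group_labels=group_labels
    )


def cr1_group_retention() -> dict[str, set[str]]:
    """Extant landscape-detectable presence of CR1 groups A-G per host class."""
    presence: dict[str, set[str]] = {}
    for line in _read("cr1_group_retention.tsv").splitlines():
        if not line or line.startswith("#"):
            continue
        group, taxa = line.split("\t")
        presence[group] = set(taxa.split(","))
    return presence
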