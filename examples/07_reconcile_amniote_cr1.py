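"""Reconcile the amniote CR1 subfamily tree against the host phylogeny.

LCA reconciliation of the packaged class-level CR1 tree counts the minimum
number of CR1 lineages that must already have existed in the amniote
ancestor, and Dollo parsimony maps where each lineage was subsequently lost.
"""

from retrochron import fixtures
from retrochron.reconcile import dollo_retention, min_ancestral_lineages

te = fixtures.cr1_te_tree()
host = fixtures.amniote_host_tree()

result = min_ancestral_lineages(te, host, "Amniota")
print(f"minimum CR1 lineages in the amniote ancestor: {result.count}")
print(f"  lineages entering from above: {len(result.crossing_edges)}")
print(f"  duplication births at Amniota: {len(result.duplication_births)}")

presence = fixtures.cr1_group_retention()
dollo = dollo_retention(host, presence, "Amniota")
print("\nDollo loss placements per CR1 group:")
for group in sorted(presence):
    losses = ", ".join(sorted(dollo.losses[group])) or "none"
    print(f"  group {group}: lost on stems of {losses}")
croc = sorted(g for g, t in presence.items() if "Crocodylia" in t)
print(f"\ncrocodilians retain {len(croc)} of {len(presence)} groups: {croc}")
# seven ancient lineages, differentially retained: crocodilians and turtles
# keep six each, birds and lepidosaurs only one
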