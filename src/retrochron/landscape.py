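"""Divergence landscapes: CpG-excluded Kimura 2-parameter distances, binned.

Each TE copy is compared with its subfamily consensus; the distance

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

distinguishes the transition proportion P from the transversion proportion
Q. Hypermutable CpG sites inflate apparent age, so both positions of every
consensus CpG dinucleotide are excluded by default. Copies are accumulated
as base pairs into 1% divergence bins over 0-50%, per subfamily group — a
proxy for the age profile of each TE lineage's activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

N_BINS = 50
GAP = "-"


@dataclass
class DivergenceEstimate:
    copy_id: str
    P: float
    Q: float
    d: float                 # math.inf when saturated
    compared_columns: int
    saturated: bool = False


@dataclass
class LandscapeTable:
    groups: list[str]
    bp: np.ndarray            # groups x 50 bins of base pairs
    discarded_bp: float = 0.0
    discarded_copies: int = 0

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=float)
        if self.bp.shape != (len(self.groups), N_BINS):
            raise ValueError("table must be groups x 50 bins")
        if (self.bp < 0).any():
            raise ValueError("negative bin mass")

    def row(self, group: str) -> np.ndarray:
        return self.bp[self.groups.index(group)]

    def to_tsv(self) -> str:
        header = "group\t" + "\t".join(f"{i}-{i+1}%" for i in range(N_BINS))
        lines = [header]
        for g, row in zip(self.groups, self.bp):
            lines.append(g + "\t" + "\t".join(f"{v:g}" for v in row))
        return "\n".join(lines) + "\n"


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = frozenset("ACGT")


def _consensus_cpg_columns(consensus_row: str) -> set[int]:
    """Columns covering a CpG dinucleotide in the ungapped consensus."""
    positions = [j for j, c in enumerate(consensus_row) if c not in (GAP, "N")]
    cpg: set[int] = set()
    for a, b in zip(positions, positions[1:]):
        if consensus_row[a] == "C" and consensus_row[b] == "G":
            cpg.add(a)
            cpg.add(b)
    return cpg


def k2p_distance(
    copy_row: str,
    consensus_row: str,
    exclude_cpg: bool = True,
    copy_id: str = "copy",
) -> DivergenceEstimate:
    """Kimura 2-parameter distance of an aligned copy/consensus pair.

    Columns with a gap or N in either row are skipped, as are (by default)
    both positions of every consensus CpG dinucleotide.
    """
    if len(copy_row) != len(consensus_row):
        raise ValueError("rows must be aligned to equal length")
    skip = _consensus_cpg_columns(consensus_row) if exclude_cpg else set()
    compared = transitions = transversions = 0
    for j, (a, b) in enumerate(zip(copy_row.upper(), consensus_row.upper())):
        if j in skip or a not in _VALID or b not in _VALID:
            continue
        compared += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if compared == 0:
        raise ValueError(f"{copy_id}: zero comparable columns")
    P = transitions / compared
    Q = transversions / compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return DivergenceEstimate(copy_id, P, Q, math.inf, compared, saturated=True)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return DivergenceEstimate(copy_id, P, Q, d, compared)


@dataclass
class LandscapeInput:
    estimate: DivergenceEstimate
    subfamily: str
    aligned_bp: int  # non-gap aligned copy bases (before CpG exclusion)


def compute_landscape(
    entries: list[LandscapeInput],
    group_map: dict[str, str],
) -> LandscapeTable:
    """Accumulate copies into (group, 1% bin) cells by aligned bp.

    Copies at or beyond 50% divergence, and saturated copies, are discarded
    and reported in the table's discard counters.
    """
    groups = sorted(set(group_map.values()))
    gidx = {g: i for i, g in enumerate(groups)}
    bp = np.zeros((len(groups), N_BINS))
    discarded_bp = 0.0
    discarded = 0
    for entry in entries:
        if entry.subfamily not in group_map:
            raise ValueError(f"subfamily {entry.subfamily!r} has no group mapping")
        est = entry.estimate
        if est.saturated or est.d >= 0.5:
            discarded += 1
            discarded_bp += entry.aligned_bp
            continue
        b = int(math.floor(100.0 * est.d))
        bp[gidx[group_map[entry.subfamily]], b] += entry.aligned_bp
    return LandscapeTable(
        groups=groups, bp=bp,
        discarded_bp=discarded_bp, discarded_copies=discarded,
    )


def aligned_bp(copy_row: str, consensus_row: str) -> int:
    """Copy bases aligned against consensus bases (gap/N columns excluded)."""
    return sum(
        1
        for a, b in zip(copy_row.upper(), consensus_row.upper())
        if a in _VALID and b in _VALID
    )


def detect_extant_activity(
    table: LandscapeTable, threshold_bp: float = 100_000.0
) -> dict[str, bool]:
    """Flag groups with more than ``threshold_bp`` in the [0,1%) bin.

    The youngest bin holds copies with essentially no divergence from their
    consensus — the signature of ongoing retroposition.
    """
    return {
        g: bool(table.bp[i, 0] > threshold_bp)
        for i, g in enumerate(table.groups)
    }
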