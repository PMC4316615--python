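"""Retroposon presence/absence markers and branch support.

A retroposon insertion shared by some taxa and cleanly absent (empty
orthologous site) from others is a nearly homoplasy-free phylogenetic
character. This module selects candidate loci with clean flanks, scores
per-locus alignments under strict orthology criteria (same target site,
element orientation and subfamily, matching target site duplication when one
exists, and a contiguous empty site for absence), assembles a marker matrix
with binary-character compatibility checking, maps markers onto host-tree
branches, and evaluates branch support with a three-way likelihood-ratio
test: under the null every conflict-capable marker picks each of the three
resolutions of the focal quartet with probability 1/3, so k clean markers
and no conflict give p = 3^-k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .io import Sequence, TECopyAnnotation
from .trees import Tree

GAP = "-"


class State(str, Enum):
    PRESENT = "P"
    ABSENT = "A"
    AMBIGUOUS = "?"


@dataclass
class LocusAlignment:
    """One per-locus cross-species alignment with element metadata."""

    locus_id: str
    rows: dict[str, str]                     # taxon -> aligned sequence
    element_span: tuple[int, int]            # alignment columns, half-open
    subfamily: str
    orientation: str
    tsd_columns: Optional[tuple[list[int], list[int]]] = None
    taxon_meta: dict[str, dict] = field(default_factory=dict)
    # taxon_meta[taxon] may carry 'subfamily' / 'orientation' observed in that
    # taxon when they differ from the locus reference (e.g. an independent
    # insertion of another subfamily at the same site)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: rows of unequal length")
        ncol = lengths.pop() if lengths else 0
        lo, hi = self.element_span
        if not (0 <= lo <= hi <= ncol):
            raise ValueError(f"{self.locus_id}: element span out of bounds")


@dataclass
class PresenceCall:
    taxon: str
    state: State
    reasons: list[str] = field(default_factory=list)


@dataclass
class Marker:
    locus_id: str
    calls: dict[str, State]
    marker_class: str = "RE"        # "RE" or "indel"
    indel_bp: Optional[int] = None  # signed length for non-TE indel markers
    subfamily: Optional[str] = None

    @property
    def present_set(self) -> frozenset[str]:
        return frozenset(t for t, s in self.calls.items() if s == State.PRESENT)

    @property
    def absent_set(self) -> frozenset[str]:
        return frozenset(t for t, s in self.calls.items() if s == State.ABSENT)

    @property
    def informative(self) -> bool:
        return bool(self.present_set) and bool(self.absent_set)


# ---------------------------------------------------------------------------
# candidate locus selection
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    candidates: list[TECopyAnnotation]
    excluded_flank_te: int = 0
    excluded_edge: int = 0
    excluded_intron: int = 0


def select_candidate_loci(
    annotations: list[TECopyAnnotation],
    genome: Sequence,
    flank: int = 750,
    intron_catalog: Optional[list[Sequence]] = None,
    max_intron_len: int = 1500,
    min_flank_identity: float = 0.8,
) -> CandidateReport:
    """Copies whose ``flank`` bp on each side overlap no other TE annotation.

    When an intron catalog is supplied, both flanks must additionally match a
    catalog sequence shorter than ``max_intron_len`` (local matcher).
    """
    by_seq: dict[str, list[TECopyAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seq_id, []).append(a)
    report = CandidateReport(candidates=[])
    short_introns = None
    if intron_catalog is not None:
        short_introns = [s for s in intron_catalog if len(s) < max_intron_len]
    for seq_id, annos in by_seq.items():
        if seq_id != genome.id:
            continue
        for a in annos:
            lo = a.start - flank
            hi = a.end + flank
            if lo < 0 or hi > len(genome):
                report.excluded_edge += 1
                continue
            clash = any(
                other is not a
                and other.start < hi
                and lo < other.end
                and not (a.start <= other.start and other.end <= a.end)
                for other in annos
            )
            if clash:
                report.excluded_flank_te += 1
                continue
            if short_introns is not None:
                from .matcher import find_copies

                left = genome.residues[lo : a.start]
                right = genome.residues[a.end : hi]
                def flank_matches(flank_seq: str) -> bool:
                    for intron in short_introns:
                        hits = find_copies(
                            intron.residues, flank_seq,
                            min_identity=min_flank_identity,
                            min_len=min(100, len(flank_seq)),
                        )
                        if hits:
                            return True
                    return False

                if not (flank_matches(left) and flank_matches(right)):
                    report.excluded_intron += 1
                    continue
            report.candidates.append(a)
    return report


# ---------------------------------------------------------------------------
# presence/absence scoring
# ---------------------------------------------------------------------------

def score_presence_absence(
    locus: LocusAlignment,
    min_element_occupancy: float = 0.9,
    max_absent_residue: int = 0,
    min_flank_occupancy: float = 0.5,
) -> list[PresenceCall]:
    """Strict orthology scoring of one locus alignment.

    PRESENT requires a filled element span of the reference subfamily in the
    reference orientation, aligned flanks, and — when the locus defines a
    target site duplication — identical TSD placement. ABSENT requires a
    gap-only element span between contiguous flanks (a clean empty site).
    Everything else is AMBIGUOUS with machine-readable reason codes.
    """
    if len(locus.rows) < 2:
        raise ValueError("scoring needs at least two taxa")
    lo, hi = locus.element_span
    calls: list[PresenceCall] = []
    for taxon, row in sorted(locus.rows.items()):
        reasons: list[str] = []
        payload = row.replace(GAP, "").replace("N", "")
        if not payload:
            calls.append(PresenceCall(taxon, State.AMBIGUOUS, ["missing_data"]))
            continue
        span = row[lo:hi]
        span_len = hi - lo
        occupied = sum(1 for c in span if c != GAP)
        left = row[:lo]
        right = row[hi:]
        left_occ = (sum(1 for c in left if c != GAP) / len(left)) if left else 0.0
        right_occ = (sum(1 for c in right if c != GAP) / len(right)) if right else 0.0
        flanks_ok = left_occ >= min_flank_occupancy and right_occ >= min_flank_occupancy
        meta = locus.taxon_meta.get(taxon, {})
        taxon_subfam = meta.get("subfamily", locus.subfamily)
        taxon_orient = meta.get("orientation", locus.orientation)

        if span_len and occupied <= max_absent_residue:
            # candidate clean absence
            if flanks_ok:
                calls.append(PresenceCall(taxon, State.ABSENT))
            else:
                calls.append(
                    PresenceCall(taxon, State.AMBIGUOUS, ["flank_missing"])
                )
            continue
        if span_len and occupied / span_len >= min_element_occupancy:
            if taxon_subfam != locus.subfamily:
                reasons.append("subtype_mismatch")
            if taxon_orient != locus.orientation:
                reasons.append("orientation_mismatch")
            if not flanks_ok:
                reasons.append("flank_missing")
            if locus.tsd_columns is not None:
                # the duplication must sit in the same placement: both TSD
                # column spans filled (sequence drift in old copies is
                # tolerated; a shifted or missing duplication is not)
                left_t, right_t = locus.tsd_columns
                left_seq = "".join(row[j] for j in left_t)
                right_seq = "".join(row[j] for j in right_t)
                if GAP in left_seq or GAP in right_seq:
                    reasons.append("tsd_mismatch")
            if reasons:
                calls.append(PresenceCall(taxon, State.AMBIGUOUS, reasons))
            else:
                calls.append(PresenceCall(taxon, State.PRESENT))
            continue
        reasons.append("partial_element" if occupied else "deletion_spanning_site")
        calls.append(PresenceCall(taxon, State.AMBIGUOUS, reasons))
    return calls


def marker_from_calls(
    locus: LocusAlignment, calls: list[PresenceCall]
) -> Marker:
    return Marker(
        locus_id=locus.locus_id,
        calls={c.taxon: c.state for c in calls},
        marker_class="RE",
        subfamily=locus.subfamily,
    )


# ---------------------------------------------------------------------------
# marker matrix & compatibility
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    taxa: list[str]
    markers: list[Marker]
    conflicts: list[tuple[str, str]]   # conflicting locus-id pairs

    def state_table(self) -> dict[str, dict[str, str]]:
        return {
            m.locus_id: {t: m.calls.get(t, State.AMBIGUOUS).value for t in self.taxa}
            for m in self.markers
        }


def _pair_conflicts(a: Marker, b: Marker) -> bool:
    defined = {
        t for t in set(a.calls) & set(b.calls)
        if a.calls[t] != State.AMBIGUOUS and b.calls[t] != State.AMBIGUOUS
    }
    pa = a.present_set & defined
    pb = b.present_set & defined
    if not pa or not pb:
        return False
    inter = pa & pb
    if not inter:
        return False
    return not (pa <= pb or pb <= pa)


def build_marker_matrix(markers: list[Marker]) -> MarkerMatrix:
    """Assemble the matrix and report all pairwise binary-character conflicts."""
    informative = [m for m in markers if m.informative]
    if not informative:
        raise ValueError("no informative markers")
    taxa = sorted({t for m in informative for t in m.calls})
    conflicts = []
    for i in range(len(informative)):
        for j in range(i + 1, len(informative)):
            if _pair_conflicts(informative[i], informative[j]):
                conflicts.append(
                    (informative[i].locus_id, informative[j].locus_id)
                )
    return MarkerMatrix(taxa=taxa, markers=informative, conflicts=conflicts)


# ---------------------------------------------------------------------------
# branch support
# ---------------------------------------------------------------------------

@dataclass
class BranchSupport:
    branch: str                     # name or leaf-set label of the clade below
    clade: frozenset[str]
    k_support: int
    k_conflict1: int
    k_conflict2: int
    statistic: float
    p_value: float
    supporting: list[str] = field(default_factory=list)


@dataclass
class SupportReport:
    branches: list[BranchSupport]
    autapomorphies: list[str]
    unassigned: list[str]


def waddell_test(
    k_support: int, k_conflict1: int, k_conflict2: int, exact: bool = False
) -> tuple[float, float]:
    """Three-way likelihood-ratio test for retroposon branch support.

    Null: each marker independently supports each of the three resolutions of
    the focal quartet with probability 1/3. The statistic is
    2 * sum k_i ln(k_i / (n/3)); p is the chi-square (df=2) survival value.
    With ``exact``, a one-sided multinomial enumeration is used instead:
    the probability of outcomes at least as extreme *in favour of the focal
    resolution* (statistic >= observed and the focal count is the maximum),
    which reproduces p = 3^-k for conflict-free patterns (k, 0, 0).
    """
    ks = (k_support, k_conflict1, k_conflict2)
    if any(k < 0 for k in ks):
        raise ValueError("counts must be non-negative")
    n = sum(ks)
    if n == 0:
        return 0.0, 1.0
    lam = 2.0 * sum(k * np.log(k / (n / 3.0)) for k in ks if k > 0)
    if not exact:
        return float(lam), float(chi2.sf(lam, df=2))
    # exact multinomial: tail probability of statistics >= observed
    from math import comb, log

    def stat(a: int, b: int, c: int) -> float:
        return 2.0 * sum(k * log(k / (n / 3.0)) for k in (a, b, c) if k > 0)

    p = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            if a >= max(b, c) and stat(a, b, c) >= lam - 1e-12:
                p += comb(n, a) * comb(n - a, b) / 3.0 ** n
    return float(lam), float(p)


def count_branch_support(
    matrix: MarkerMatrix, host_tree: Tree, exact: bool = False
) -> SupportReport:
    """Tally marker support for each internal host-tree branch.

    A marker supports a branch when its PRESENT set (restricted to its
    non-ambiguous taxa) equals the clade below the branch and at least one
    taxon outside is ABSENT. The two conflict categories of the test are the
    two alternative resolutions of the quartet around the focal branch
    (each child clade joined with the focal clade's sister instead).
    """
    tree_taxa = set(host_tree.leaf_names())
    if not set(matrix.taxa) <= tree_taxa:
        missing = set(matrix.taxa) - tree_taxa
        raise ValueError(f"matrix taxa not in tree: {sorted(missing)}")

    def restricted(marker: Marker, target: frozenset[str]) -> Optional[bool]:
        defined = {
            t for t, s in marker.calls.items() if s != State.AMBIGUOUS
        }
        pres = marker.present_set
        if not pres or not (marker.absent_set):
            return None
        return pres == (target & defined) and bool(defined - target)

    branches: list[BranchSupport] = []
    autapomorphies = [
        m.locus_id for m in matrix.markers if len(m.present_set) == 1
    ]
    assigned: set[str] = set(autapomorphies)
    for node in host_tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        clade = host_tree.clade_leaf_names(node) & set(matrix.taxa)
        if len(clade) < 2 or len(clade) == len(matrix.taxa):
            continue
        # quartet parts: the two child clades, the sister group, the rest
        child_clades = [
            host_tree.clade_leaf_names(c) & set(matrix.taxa)
            for c in node.children
        ]
        siblings = [c for c in node.parent.children if c is not node]
        sister = frozenset().union(
            *[host_tree.clade_leaf_names(s) for s in siblings]
        ) & set(matrix.taxa)
        alt_sets = []
        if len(child_clades) == 2 and sister:
            alt_sets = [
                frozenset(child_clades[0]) | frozenset(sister),
                frozenset(child_clades[1]) | frozenset(sister),
            ]
        k = [0, 0, 0]
        supporting: list[str] = []
        for m in matrix.markers:
            if len(m.present_set) == 1:
                continue
            if restricted(m, frozenset(clade)):
                k[0] += 1
                supporting.append(m.locus_id)
                assigned.add(m.locus_id)
            else:
                for ai, alt in enumerate(alt_sets):
                    if restricted(m, alt):
                        k[ai + 1] += 1
                        assigned.add(m.locus_id)
        lam, p = waddell_test(k[0], k[1], k[2], exact=exact)
        branches.append(
            BranchSupport(
                branch=node.name or "+".join(sorted(clade)),
                clade=frozenset(clade),
                k_support=k[0],
                k_conflict1=k[1],
                k_conflict2=k[2],
                statistic=lam,
                p_value=p,
                supporting=supporting,
            )
        )
    unassigned = [
        m.locus_id for m in matrix.markers if m.locus_id not in assigned
    ]
    return SupportReport(
        branches=branches, autapomorphies=autapomorphies, unassigned=unassigned
    )


# ---------------------------------------------------------------------------
# perfect phylogeny check (constructive compatibility verification)
# ---------------------------------------------------------------------------

def perfect_phylogeny_exists(matrix: MarkerMatrix) -> bool:
    """True iff the PRESENT sets are pairwise nested or disjoint.

    For binary characters with known ancestral state (absent), pairwise
    compatibility of all characters is equivalent to the existence of a
    perfect phylogeny (the laminar-family construction).
    """
    sets = [m.present_set for m in matrix.markers if m.informative]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a & b and not (a <= b or b <= a):
                return False
    return True
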