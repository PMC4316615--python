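"""TE subfamily consensus building and clustering.

A seed repeat is located in a genome (``find_copies`` from the matcher), the
top copies are extracted with flanking sequence, multiply aligned, and a
majority-rule consensus is called. An element boundary has been reached when
the flanking alignment columns are highly variable — copies inserted at
unrelated loci drag unrelated flanks into the alignment — so each terminus is
flagged complete when mean pairwise column identity over a flank window
drops below a threshold; incomplete ends trigger another extension round.
Finished consensus sequences are grouped into subfamilies by greedy centroid
clustering at 95% global identity.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .io import Sequence, fasta_string, read_fasta
from .matcher import Hit, find_copies, global_identity

GAP = "-"


@dataclass
class ConsensusModel:
    sequence: Sequence
    complete_5prime: bool
    complete_3prime: bool
    support: int
    iteration_count: int = 1

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if not self.sequence.residues:
            raise ValueError("consensus sequence must be non-empty")


def align_sequences(seqs: list[Sequence]) -> list[Sequence]:
    """Multiple alignment of the given sequences.

    Equal-length inputs are returned as-is (already columnwise comparable);
    otherwise mafft is invoked. Row order is preserved.
    """
    if len(seqs) == 1:
        return list(seqs)
    if len({len(s) for s in seqs}) == 1:
        return list(seqs)
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH; required for unequal-length MSA")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        inp.write_text(fasta_string(seqs))
        # accurate G-INS-i mode: copy sets are small, and spurious gaps in
        # fast progressive mode directly corrupt the majority consensus
        proc = subprocess.run(
            [mafft, "--quiet", "--globalpair", "--maxiterate", "1000", str(inp)],
            capture_output=True, text=True, check=True,
        )
    aligned = {
        s.id: s for s in read_fasta_from_text(proc.stdout)
    }
    return [aligned[s.id] for s in seqs]


def read_fasta_from_text(text: str) -> list[Sequence]:
    import io as _io

    return read_fasta(_io.StringIO(text))


def majority_consensus(rows: list[str]) -> str:
    """Per-column majority base; gap only on strict majority, base ties A<C<G<T.

    'N' is treated as missing and contributes to no count; columns whose
    winner is a gap are removed.
    """
    if not rows:
        raise ValueError("no rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("rows of unequal length")
    out = []
    for j in range(ncol):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, GAP: 0}
        informative = 0
        for r in rows:
            ch = r[j]
            if ch == "N":
                continue
            counts[ch] = counts.get(ch, 0) + 1
            informative += 1
        if informative == 0:
            continue
        if counts[GAP] * 2 > informative:  # strict gap majority
            continue
        best = max("ACGT", key=lambda b: (counts[b], ))
        # alphabetical tie-break is implicit: max() keeps the first of equals
        if counts[best] == 0:
            continue
        out.append(best)
    return "".join(out)


def column_identities(rows: list[str]) -> list[float]:
    """Mean pairwise identity per alignment column.

    'N' contributes nothing; a column the aligner could not stack (fewer than
    two residues) is maximally variable (0.0).
    """
    from collections import Counter

    out = []
    for j in range(len(rows[0])):
        chars = [r[j] for r in rows if r[j] not in (GAP, "N")]
        n = len(chars)
        if n < 2:
            out.append(0.0)
            continue
        pairs = n * (n - 1) / 2
        same = sum(k * (k - 1) / 2 for k in Counter(chars).values())
        out.append(same / pairs)
    return out


def check_completeness(
    rows: list[str],
    core_span: tuple[int, int],
    window: int = 50,
    theta: float = 0.6,
) -> tuple[bool, bool]:
    """Flank-variability completeness test.

    An end is complete iff the mean pairwise column identity over ``window``
    flank columns adjacent to that end is below ``theta`` — variable flanks
    mean the copies' own genomic neighborhoods have been reached, i.e. the
    element boundary lies inside the aligned core.
    """
    import warnings

    lo, hi = core_span
    ncol = len(rows[0])
    ident = column_identities(rows)
    left_cols = ident[max(0, lo - window) : lo]
    right_cols = ident[hi : min(ncol, hi + window)]
    complete5 = (
        len(left_cols) >= window and sum(left_cols) / len(left_cols) < theta
    )
    complete3 = (
        len(right_cols) >= window and sum(right_cols) / len(right_cols) < theta
    )
    if len(left_cols) < window or len(right_cols) < window:
        warnings.warn(
            "fewer flank columns than the test window; end(s) reported incomplete",
            stacklevel=2,
        )
    return complete5, complete3


def _extend_core(
    ident: list[float], core: tuple[int, int], window: int, theta: float
) -> tuple[int, int]:
    """Grow the core span over flank windows that stay conserved.

    Copies of one element share the rest of the element beyond any seed
    sub-sequence, so conserved flanking columns belong to the element; growth
    stops at the first window whose mean identity drops below ``theta``, and
    straggling variable columns at the new ends are trimmed back.
    """
    lo, hi = core
    while lo >= window:
        chunk = ident[lo - window : lo]
        if sum(chunk) / window < theta:
            break
        lo -= window
    while hi + window <= len(ident):
        chunk = ident[hi : hi + window]
        if sum(chunk) / window < theta:
            break
        hi += window
    while lo < hi and ident[lo] < theta:
        lo += 1
    while hi > lo and ident[hi - 1] < theta:
        hi -= 1
    return lo, hi


def build_consensus(
    genome: Sequence,
    hits: list[Hit],
    max_hits: int = 50,
    flank: int = 1000,
    window: int = 50,
    theta: float = 0.6,
) -> ConsensusModel:
    """Majority-rule consensus over the top ``max_hits`` copies with flanks."""
    if not hits:
        raise ValueError("at least one hit required")
    top = sorted(hits, key=lambda h: -h.matches)[:max_hits]
    copies = []
    clipped_left = clipped_right = 0
    for i, h in enumerate(top):
        lo = max(0, h.target_start - flank)
        hi = min(len(genome), h.target_end + flank)
        sub = genome.residues[lo:hi]
        if h.strand == "-":
            from .io import reverse_complement

            sub = reverse_complement(sub)
        copies.append(Sequence(id=f"copy{i}", residues=sub))
    aligned = align_sequences(copies)
    rows = [s.residues for s in aligned]
    # seed core: columns covered by the un-flanked copy of the best hit,
    # then grown over conserved flank columns (element sequence shared by
    # all copies beyond the seed span)
    core_lo, core_hi = _core_span(rows, top, flank, genome)
    if len(copies) > 1:
        ident = column_identities(rows)
        core_lo, core_hi = _extend_core(ident, (core_lo, core_hi), window, theta)
    cons = majority_consensus([r[core_lo:core_hi] for r in rows])
    c5, c3 = (False, False)
    if len(copies) > 1:
        c5, c3 = check_completeness(rows, (core_lo, core_hi), window, theta)
    if not cons:
        cons = copies[0].residues
    return ConsensusModel(
        sequence=Sequence(id="consensus", residues=cons),
        complete_5prime=c5,
        complete_3prime=c3,
        support=len(copies),
    )


def _core_span(rows: list[str], hits: list[Hit], flank: int, genome: Sequence) -> tuple[int, int]:
    """Alignment-column span of the element core of the best (first) copy."""
    h = hits[0]
    left_pad = min(flank, h.target_start)
    core_len = h.target_end - h.target_start
    row = rows[0]
    # walk the aligned row: skip left_pad residues, then span core_len residues
    seen = 0
    lo = 0
    for j, ch in enumerate(row):
        if seen == left_pad:
            lo = j
            break
        if ch != GAP:
            seen += 1
    else:
        lo = len(row)
    seen = 0
    hi = lo
    for j in range(lo, len(row)):
        if seen == core_len:
            hi = j
            break
        if row[j] != GAP:
            seen += 1
    else:
        hi = len(row)
    return lo, hi


def iterate_consensus(
    genome: Sequence,
    seed: Sequence,
    min_identity: float = 0.8,
    min_len: int = 50,
    max_iterations: int = 10,
    extension_step: int = 500,
    flank: int = 1000,
    max_hits: int = 50,
) -> ConsensusModel:
    """BLAST/extract/align/consensus loop until both termini test complete."""
    query = seed
    model = None
    cur_flank = flank
    for it in range(1, max_iterations + 1):
        hits = find_copies(genome.residues, query.residues,
                           min_identity=min_identity, min_len=min_len)
        if not hits:
            if model is not None:
                return model
            raise ValueError("seed finds no copies in the genome")
        model = build_consensus(genome, hits, max_hits=max_hits, flank=cur_flank)
        model.iteration_count = it
        if model.complete_5prime and model.complete_3prime:
            return model
        query = model.sequence
        cur_flank += extension_step
    return model


@dataclass
class SubfamilyCluster:
    centroid_id: str
    members: list[ConsensusModel]
    merged: ConsensusModel


def cluster_subfamilies(
    consensi: list[ConsensusModel], threshold: float = 0.95
) -> list[SubfamilyCluster]:
    """Greedy centroid clustering at a global-identity threshold.

    Inputs are processed longest-first (ties broken lexicographically by id);
    a candidate joins the first centroid it exceeds ``threshold`` identity
    with, where identity is matches over global-alignment length (gaps count
    against identity). Each cluster's consensus is rebuilt by majority rule
    over its members.
    """
    if not consensi:
        raise ValueError("at least one consensus required")
    ordered = sorted(
        consensi, key=lambda m: (-len(m.sequence.residues), m.sequence.id)
    )
    clusters: list[SubfamilyCluster] = []
    for model in ordered:
        placed = False
        for cl in clusters:
            ident = global_identity(
                model.sequence.residues, cl.merged.sequence.residues
            )
            if ident > threshold:
                cl.members.append(model)
                cl.merged = _merge_cluster(cl)
                placed = True
                break
        if not placed:
            clusters.append(
                SubfamilyCluster(
                    centroid_id=model.sequence.id,
                    members=[model],
                    merged=model,
                )
            )
    return clusters


def _merge_cluster(cl: SubfamilyCluster) -> ConsensusModel:
    seqs = [
        Sequence(id=f"m{i}", residues=m.sequence.residues)
        for i, m in enumerate(cl.members)
    ]
    aligned = align_sequences(seqs)
    merged = majority_consensus([s.residues for s in aligned])
    return ConsensusModel(
        sequence=Sequence(id=cl.centroid_id, residues=merged),
        complete_5prime=all(m.complete_5prime for m in cl.members),
        complete_3prime=all(m.complete_3prime for m in cl.members),
        support=sum(m.support for m in cl.members),
    )
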