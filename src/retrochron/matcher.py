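"""Seed-and-extend local DNA matcher.

Finds occurrences of a query sequence (a consensus, a seed repeat) inside a
target sequence (a genome fragment, a survey read). Exact k-mer seeds
(default 11-mers) anchor candidate diagonals; each anchor is extended
ungapped in both directions under an X-drop rule, and the best
non-overlapping hits above identity/length floors are reported strand-aware.

The simulated data this package analyses contains substitutions but no
within-copy indels, so ungapped extension recovers copies exactly; an
optional gapped refinement via edlib re-scores each candidate span for
robustness on externally supplied data.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .io import reverse_complement

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class Hit:
    """A local match of query inside target (target coordinates, half-open)."""

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str  # orientation of the query copy in the target
    matches: int
    identity: float

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if _DNA.issuperset(kmer):
            index.setdefault(kmer, []).append(i)
    return index


def _extend(target: str, query: str, tpos: int, qpos: int, k: int, xdrop: int,
            mismatch_penalty: int = 2) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension around an exact k-mer seed.

    Returns (tstart, tend, qstart, qend, matches) of the best-scoring
    ungapped segment containing the seed.
    """
    # right extension
    score = best = k
    ti, qi = tpos + k, qpos + k
    best_t, best_q = ti, qi
    while ti < len(target) and qi < len(query):
        score += 1 if target[ti] == query[qi] else -mismatch_penalty
        ti += 1
        qi += 1
        if score > best:
            best, best_t, best_q = score, ti, qi
        elif best - score > xdrop:
            break
    tend, qend = best_t, best_q
    # left extension
    score = best = 0
    ti, qi = tpos - 1, qpos - 1
    best_t, best_q = tpos, qpos
    while ti >= 0 and qi >= 0:
        score += 1 if target[ti] == query[qi] else -mismatch_penalty
        if score > best:
            best, best_t, best_q = score, ti, qi
        elif best - score > xdrop:
            break
        ti -= 1
        qi -= 1
    tstart, qstart = best_t, best_q
    matches = sum(
        1 for a, b in zip(target[tstart:tend], query[qstart:qend]) if a == b
    )
    return tstart, tend, qstart, qend, matches


def _refine_gapped(target: str, query: str, hit: Hit, pad: int = 30) -> Hit:
    """Re-locate a candidate span with edlib (gapped) and recompute identity."""
    qseq = query[hit.query_start : hit.query_end]
    lo = max(0, hit.target_start - pad)
    hi = min(len(target), hit.target_end + pad)
    res = edlib.align(qseq, target[lo:hi], mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return hit
    s, e = res["locations"][0]
    e += 1
    alen = max(e - s, len(qseq))
    matches = alen - res["editDistance"]
    refined = Hit(
        target_start=lo + s,
        target_end=lo + e,
        query_start=hit.query_start,
        query_end=hit.query_end,
        strand=hit.strand,
        matches=matches,
        identity=matches / alen if alen else 0.0,
    )
    return refined if refined.matches > hit.matches else hit


def find_copies(
    target: str,
    query: str,
    min_identity: float = 0.8,
    min_len: int = 50,
    seed_len: int = 11,
    xdrop: int = 20,
    gapped: bool = False,
) -> list[Hit]:
    """Best-scoring non-overlapping local matches of ``query`` in ``target``.

    Hits are reported in target coordinates with the strand on which the
    query matched; overlapping candidates are resolved greedily by match
    count.
    """
    if len(query) < seed_len:
        raise ValueError(
            f"query length {len(query)} shorter than seed length {seed_len}"
        )
    target = target.upper()
    candidates: list[Hit] = []
    index = _kmer_index(target, seed_len)
    for strand in "+-":
        q = query.upper() if strand == "+" else reverse_complement(query.upper())
        covered: dict[int, list[tuple[int, int]]] = {}
        for qpos in range(len(q) - seed_len + 1):
            kmer = q[qpos : qpos + seed_len]
            for tpos in index.get(kmer, ()):
                diag = tpos - qpos
                if any(a <= tpos < b for a, b in covered.get(diag, ())):
                    continue
                tstart, tend, qstart, qend, matches = _extend(
                    target, q, tpos, qpos, seed_len, xdrop
                )
                covered.setdefault(diag, []).append((tstart, tend))
                length = tend - tstart
                if length == 0:
                    continue
                hit = Hit(
                    target_start=tstart,
                    target_end=tend,
                    query_start=qstart if strand == "+" else len(q) - qend,
                    query_end=qend if strand == "+" else len(q) - qstart,
                    strand=strand,
                    matches=matches,
                    identity=matches / length,
                )
                if gapped:
                    hit = _refine_gapped(target, q, Hit(
                        target_start=tstart, target_end=tend,
                        query_start=qstart, query_end=qend,
                        strand=strand, matches=matches,
                        identity=matches / length,
                    ))
                    if strand == "-":
                        hit = Hit(
                            target_start=hit.target_start,
                            target_end=hit.target_end,
                            query_start=len(q) - hit.query_end,
                            query_end=len(q) - hit.query_start,
                            strand="-",
                            matches=hit.matches,
                            identity=hit.identity,
                        )
                candidates.append(hit)
    kept: list[Hit] = []
    for hit in sorted(candidates, key=lambda h: (-h.matches, h.target_start)):
        if hit.identity < min_identity or hit.length < min_len:
            continue
        if any(
            hit.target_start < k.target_end and k.target_start < hit.target_end
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.target_start)
    return kept


def global_identity(a: str, b: str) -> float:
    """Identity of the global pairwise alignment: matches / alignment length."""
    a, b = a.upper(), b.upper()
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    alen = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return matches / alen if alen else 0.0
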