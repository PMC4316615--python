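"""TE quantification from low-coverage survey reads.

Unassembled reads (~0.2x coverage, 100 bp) are matched strand-aware against
a library of subfamily consensus sequences; hits shorter than 30 bp are
dropped and cumulative matched bp per subfamily recorded. Because short-read
detectability is biased the same way in every library, per-subfamily
conversion coefficients derived from one species with both a survey library
and an assembled genome (c_s = assembly_bp_s / survey_bp_s) turn the other
libraries' counts into genome-wide bp estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import Sequence
from .matcher import find_copies


@dataclass(frozen=True)
class SurveyHit:
    read_id: str
    subfamily: str
    matched_bp: int
    identity: float

    def __post_init__(self) -> None:
        if self.matched_bp < 30:
            raise ValueError("survey hits must span at least 30 bp")
        if not 0 < self.identity <= 1:
            raise ValueError("identity must lie in (0,1]")


@dataclass
class SurveyResult:
    hits: list[SurveyHit]
    bp_per_subfamily: dict[str, int]
    reads_per_subfamily: dict[str, int]


def match_reads(
    reads: list[Sequence],
    library: list[Sequence],
    min_hit_len: int = 30,
    min_identity: float = 0.7,
    best_only: bool = False,
    seed_len: int = 11,
) -> SurveyResult:
    """Match each read against every library consensus.

    Per read, the best-scoring non-overlapping hits (on read coordinates)
    are kept; ``best_only`` restricts to the single best hit per read. Hits
    shorter than ``min_hit_len`` are dropped.
    """
    if not reads or not library:
        raise ValueError("reads and library must be non-empty")
    hits: list[SurveyHit] = []
    bp: dict[str, int] = {s.id: 0 for s in library}
    nreads: dict[str, int] = {s.id: 0 for s in library}
    for read in reads:
        if len(read) < seed_len:
            continue
        candidates = []
        for cons in library:
            for h in find_copies(
                read.residues, cons.residues,
                min_identity=min_identity, min_len=min_hit_len,
                seed_len=seed_len,
            ):
                candidates.append((h, cons.id))
        candidates.sort(key=lambda hc: (-hc[0].matches, hc[0].target_start))
        kept: list[tuple] = []
        for h, subfam in candidates:
            if any(
                h.target_start < k.target_end and k.target_start < h.target_end
                for k, _ in kept
            ):
                continue
            kept.append((h, subfam))
            if best_only:
                break
        seen_subfams = set()
        for h, subfam in kept:
            hits.append(
                SurveyHit(
                    read_id=read.id,
                    subfamily=subfam,
                    matched_bp=h.length,
                    identity=h.identity,
                )
            )
            bp[subfam] = bp.get(subfam, 0) + h.length
            if subfam not in seen_subfams:
                nreads[subfam] = nreads.get(subfam, 0) + 1
                seen_subfams.add(subfam)
    return SurveyResult(hits=hits, bp_per_subfamily=bp, reads_per_subfamily=nreads)


@dataclass
class CalibrationTable:
    coefficients: dict[str, float]
    uncalibratable: list[str] = field(default_factory=list)


def calibrate(
    survey_bp: dict[str, float], assembly_bp: dict[str, float]
) -> CalibrationTable:
    """Per-subfamily conversion coefficients c_s = assembly_bp_s / survey_bp_s."""
    if any(v < 0 for v in survey_bp.values()) or any(
        v < 0 for v in assembly_bp.values()
    ):
        raise ValueError("negative input quantities")
    coef: dict[str, float] = {}
    flagged: list[str] = []
    for subfam in sorted(set(survey_bp) | set(assembly_bp)):
        s = survey_bp.get(subfam, 0.0)
        a = assembly_bp.get(subfam, 0.0)
        if s > 0:
            coef[subfam] = a / s
        else:
            flagged.append(subfam)
    return CalibrationTable(coefficients=coef, uncalibratable=flagged)


def estimate_genome_content(
    survey_bp: dict[str, float], table: CalibrationTable
) -> dict[str, float]:
    """Genome-wide bp estimates E_s = c_s * survey_bp_s.

    Subfamilies without a coefficient are omitted with a warning; these are
    rough estimates by construction — short-read detection biases cancel only
    to the extent they match the calibration species.
    """
    import warnings

    out: dict[str, float] = {}
    missing = []
    for subfam, s in survey_bp.items():
        if subfam in table.coefficients:
            out[subfam] = table.coefficients[subfam] * s
        elif s > 0:
            missing.append(subfam)
    if missing:
        warnings.warn(
            f"no calibration coefficient for: {sorted(missing)}; omitted",
            stacklevel=2,
        )
    return out
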