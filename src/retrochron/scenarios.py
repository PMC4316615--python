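"""Reference study scenarios: end-to-end exercises at fixed conditions.

Each function builds a small synthetic study with the generator defaults
this package treats as its standard conditions (activity periods, sample
sizes, 0.2x / 100-bp survey sampling, CpG-elevated substitution), runs the
relevant analysis chain, and returns the headline quantities. The test
suite asserts on these results and ``scripts/acceptance.py`` reports them;
both therefore recompute everything from scratch through the public API.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from .consensus import ConsensusModel, build_consensus, cluster_subfamilies
from .io import Sequence, read_fasta, reverse_complement
from .landscape import LandscapeInput, aligned_bp, k2p_distance
from .markers import (
    LocusAlignment,
    State,
    build_marker_matrix,
    count_branch_support,
    marker_from_calls,
    score_presence_absence,
)
from .matcher import find_copies, global_identity
from .simulate import (
    SimConfig,
    SubfamilySpec,
    emit_locus_alignments,
    simulate_history,
    simulate_nesting_counts,
    simulate_survey_reads,
)
from .survey import calibrate, estimate_genome_content, match_reads
from .tint import NestingMatrix, fit_activity_model
from .trees import read_newick

CROC_TREE = (
    "((Alligator:3,(Crocodylus:2,Gavialis:2)Longirostres:1)Crocodylia:2,"
    "Gallus:5)RootNode;"
)


# ---------------------------------------------------------------------------
# TinT activity recovery
# ---------------------------------------------------------------------------

def tint_recovery_study(
    n_replicates: int = 20,
    n_subfamilies: int = 6,
    n_insertions: int = 600,
    base_seed: int = 1000,
) -> list[float]:
    """Rank-recovery of Gaussian activity means from nesting counts.

    Per replicate: six subfamilies with unit activity s.d. and true means
    spaced by at least one s.d.; ~600 nestings generated mechanistically;
    the multinomial activity model is fitted and the Spearman correlation
    between true and fitted means recorded.
    """
    rhos = []
    for rep in range(n_replicates):
        seed = base_seed + rep
        rng = np.random.default_rng(seed)
        mus = np.cumsum(rng.uniform(1.0, 2.0, size=n_subfamilies))
        specs = [
            SubfamilySpec(f"S{i}", mu=float(m), sigma=1.0, rate=1.0)
            for i, m in enumerate(mus)
        ]
        counts = simulate_nesting_counts(specs, n_insertions=n_insertions, seed=seed)
        matrix = NestingMatrix.from_dict(
            counts, subfamilies=[s.name for s in specs]
        )
        fit = fit_activity_model(matrix, seed=seed)
        fitted = {e.subfamily: e.mu for e in fit.estimates}
        true = [float(m) for s, m in zip(specs, mus) if s.name in fitted]
        est = [fitted[s.name] for s in specs if s.name in fitted]
        rhos.append(float(spearmanr(true, est).statistic))
    return rhos


# ---------------------------------------------------------------------------
# CpG-excluded divergence
# ---------------------------------------------------------------------------

@dataclass
class CpGStudyResult:
    mean_d_excluded: float
    mean_d_included: float
    n_copies: int


def cpg_divergence_study(seed: int = 9) -> CpGStudyResult:
    """Paired CpG-excluded vs -included divergence on one simulated lineage."""
    tree = read_newick("((X:1.0)Tip:2.0)Root;")
    cfg = SimConfig(
        host_tree=tree,
        subfamilies=[SubfamilySpec("S", mu=1.0, sigma=0.5, rate=60,
                                   element_length=600)],
        ancestral_genome_length=30_000,
        subst_rate=0.03,
        cpg_multiplier=12.0,
        p_tsd=0.0,
        seed=seed,
    )
    sim = simulate_history(cfg)
    d_ex, d_in = [], []
    genome = sim.genome("X")
    for rec in sim.registry.insertions.values():
        frags = [
            a for a in sim.annotations("X")
            if a.fragment_group == f"ins{rec.insertion_id}"
        ]
        copy = "".join(genome.residues[a.start:a.end] for a in frags)
        if len(copy) != len(rec.element_ids):
            continue
        if rec.strand == "-":
            copy = reverse_complement(copy)
        ref = sim.masters[rec.subfamily][-len(copy):]
        ex = k2p_distance(copy, ref, exclude_cpg=True)
        inc = k2p_distance(copy, ref, exclude_cpg=False)
        if not ex.saturated and not inc.saturated:
            d_ex.append(ex.d)
            d_in.append(inc.d)
    return CpGStudyResult(
        mean_d_excluded=float(np.mean(d_ex)),
        mean_d_included=float(np.mean(d_in)),
        n_copies=len(d_ex),
    )


# ---------------------------------------------------------------------------
# survey calibration round-trip
# ---------------------------------------------------------------------------

@dataclass
class SurveyStudyResult:
    calibration_exact: bool
    max_rel_error: float
    per_subfamily_errors: dict[str, float]


def survey_calibration_study(seed: int = 1) -> SurveyStudyResult:
    """Two sister species, one 'assembled' and one survey-sequenced.

    Most TE activity predates the split, so both genomes carry comparable
    loads (>=50 kb per subfamily). Conversion coefficients derived on the
    assembled species are applied to the other's 0.2x / 100-bp read survey
    and compared with its true annotated content.
    """
    host = read_newick("((Asin:1.0,Amis:1.0)Alligatoridae:4.0)Root;")
    specs = [
        SubfamilySpec("CR1-A", mu=2.0, sigma=0.8, rate=1300, element_length=900),
        SubfamilySpec("CR1-B", mu=3.0, sigma=0.7, rate=1500, element_length=700),
    ]
    cfg = SimConfig(
        host_tree=host, subfamilies=specs,
        ancestral_genome_length=200_000, subst_rate=0.012, seed=seed,
    )
    sim = simulate_history(cfg)
    truth = {t: {} for t in sim.taxon_names}
    for t in sim.taxon_names:
        for a in sim.annotations(t):
            truth[t][a.subfamily] = truth[t].get(a.subfamily, 0) + a.length
    library = [Sequence(n, s) for n, s in sim.masters.items()]
    survey_bp = {}
    for t in sim.taxon_names:
        reads = simulate_survey_reads(sim.genome(t), 100, 0.2, seed=seed + 500)
        survey_bp[t] = match_reads(reads, library).bp_per_subfamily
    table = calibrate(
        survey_bp["Asin"], {k: float(v) for k, v in truth["Asin"].items()}
    )
    self_est = estimate_genome_content(survey_bp["Asin"], table)
    exact = all(
        abs(self_est[s] - truth["Asin"][s]) < 1e-6 for s in self_est
    )
    cross = estimate_genome_content(survey_bp["Amis"], table)
    errors = {
        s: abs(v - truth["Amis"][s]) / truth["Amis"][s] for s, v in cross.items()
    }
    return SurveyStudyResult(
        calibration_exact=exact,
        max_rel_error=max(errors.values()),
        per_subfamily_errors=errors,
    )


# ---------------------------------------------------------------------------
# marker pipeline against simulator truth
# ---------------------------------------------------------------------------

@dataclass
class MarkerStudyResult:
    n_loci_scored: int
    n_informative: int
    n_conflicts: int
    call_accuracy: float
    branch_mapping_correct: bool


def marker_truth_study(seed: int = 3) -> MarkerStudyResult:
    """Score simulated loci and check calls/branch mapping against truth."""
    host = read_newick(CROC_TREE)
    specs = [
        SubfamilySpec("CR1-old", mu=1.0, sigma=1.0, rate=25, element_length=800),
        SubfamilySpec("CR1-young", mu=4.0, sigma=0.8, rate=25, element_length=600),
    ]
    cfg = SimConfig(
        host_tree=host, subfamilies=specs,
        ancestral_genome_length=40_000, subst_rate=0.005, seed=seed,
    )
    sim = simulate_history(cfg)
    markers, loci = [], []
    ok = bad = 0
    for locus in emit_locus_alignments(sim, flank=300):
        if not locus.intact or locus.clipped:
            continue
        la = LocusAlignment(
            locus_id=locus.locus_id,
            rows=locus.rows,
            element_span=locus.element_span,
            subfamily=locus.subfamily,
            orientation=locus.orientation,
            tsd_columns=locus.tsd_columns,
        )
        calls = score_presence_absence(la)
        for c in calls:
            truth = State.PRESENT if c.taxon in locus.present_taxa else State.ABSENT
            if c.state == truth:
                ok += 1
            else:
                bad += 1
        markers.append(marker_from_calls(la, calls))
        loci.append(locus)
    matrix = build_marker_matrix(markers)
    report = count_branch_support(matrix, host)
    truth_branch = {
        f"locus_ins{r.insertion_id}": r.branch
        for r in sim.registry.insertions.values()
    }
    supported = {lid: b.branch for b in report.branches for lid in b.supporting}
    expected = {m.locus_id for m in matrix.markers if len(m.present_set) > 1}
    mapping_ok = (
        set(supported) == expected
        and all(truth_branch[lid] == br for lid, br in supported.items())
    )
    return MarkerStudyResult(
        n_loci_scored=len(loci),
        n_informative=len(matrix.markers),
        n_conflicts=len(matrix.conflicts),
        call_accuracy=ok / (ok + bad) if ok + bad else 0.0,
        branch_mapping_correct=mapping_ok,
    )


# ---------------------------------------------------------------------------
# consensus recovery and clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusStudyResult:
    identity_to_master: float
    n_clusters_similar_pair: int
    n_clusters_distant_pair: int


def consensus_recovery_study(seed: int = 3) -> ConsensusStudyResult:
    """Rebuild a 500-bp master from 10 copies at 5% divergence and cluster."""
    rng = np.random.default_rng(seed)

    def rand_dna(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def mutate(s, frac):
        out = list(s)
        for i in rng.choice(len(out), size=int(round(frac * len(out))),
                            replace=False):
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    master = rand_dna(500)
    parts = [rand_dna(400)]
    for _ in range(10):
        parts.append(mutate(master, 0.05))
        parts.append(rand_dna(400))
    genome = Sequence("g", "".join(parts))
    hits = find_copies(genome.residues, master, min_identity=0.8, min_len=200)
    model = build_consensus(genome, hits, flank=100)
    identity = global_identity(model.sequence.residues, master)

    def cm(name, s):
        return ConsensusModel(Sequence(name, s), True, True, 1)

    similar = cluster_subfamilies(
        [cm("a", master), cm("b", mutate(master, 0.02))], threshold=0.95
    )
    distant = cluster_subfamilies(
        [cm("a", master), cm("b", mutate(master, 0.10))], threshold=0.95
    )
    return ConsensusStudyResult(
        identity_to_master=identity,
        n_clusters_similar_pair=len(similar),
        n_clusters_distant_pair=len(distant),
    )


# ---------------------------------------------------------------------------
# external per-locus alignment scoring (published supplementary data layout)
# ---------------------------------------------------------------------------

def score_locus_directory(
    directory: Path | str, metadata_tsv: Path | str
) -> dict:
    """Score a directory of per-locus alignment FASTAs under strict criteria.

    ``metadata_tsv`` columns: locus_id, element_start, element_end (alignment
    columns, 0-based half-open), subfamily, orientation, marker_class.
    Returns summary counts: loci scored, informative presence/absence
    patterns, CR1-classified patterns, and markers supporting each clade.
    """
    directory = Path(directory)
    meta = {}
    for line in Path(metadata_tsv).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        lid, lo, hi, subfam, orient, mclass = line.split("\t")[:6]
        meta[lid] = (int(lo), int(hi), subfam, orient, mclass)
    markers = []
    n_scored = 0
    n_cr1 = 0
    for fasta in sorted(directory.glob("*.fa*")):
        lid = fasta.stem
        if lid not in meta:
            continue
        lo, hi, subfam, orient, mclass = meta[lid]
        rows = {s.id: s.residues for s in read_fasta(fasta)}
        la = LocusAlignment(
            locus_id=lid, rows=rows, element_span=(lo, hi),
            subfamily=subfam, orientation=orient,
        )
        marker = marker_from_calls(la, score_presence_absence(la))
        n_scored += 1
        if subfam.upper().startswith("CR1"):
            n_cr1 += marker.informative
        markers.append(marker)
    informative = [m for m in markers if m.informative]
    out = {
        "loci_scored": n_scored,
        "informative_patterns": len(informative),
        "cr1_patterns": n_cr1,
    }
    return out
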