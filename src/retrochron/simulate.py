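"""Synthetic TE insertion histories along a dated host tree.

The generator plays forward the processes the downstream analyses assume:

* each TE subfamily *s* has a Gaussian activity period — insertions on a host
  branch arrive as a Poisson process with intensity ``rate_s`` times the
  Normal(mu_s, sigma_s) density restricted to the branch's time interval;
* insertion sites are uniform over the current genome; a site inside an
  existing copy produces a nested insertion and splits the host copy into two
  linked fragments;
* new copies are 5'-truncated (reverse transcription rarely completes), may
  carry a target site duplication, and land on either strand;
* substitutions accumulate under a two-parameter (transition/transversion)
  model with an elevated rate at CpG dinucleotides; no indels occur outside
  insertion events, and copies are never excised;
* optional lineage-loss events purge all copies of a subfamily from one host
  lineage.

Every base ever created carries a globally unique column id, so exact
multi-species alignments, per-taxon annotations and a complete truth registry
(for oracle tests) fall out of the bookkeeping rather than from re-alignment.

Time runs from 0 at the host-tree root toward the present (larger = younger);
all modules share this convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import numpy as np
from scipy.stats import norm

from .io import Sequence, TECopyAnnotation, reverse_complement
from .trees import Tree, TreeNode

_START = -1  # virtual column preceding the genome
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {65: 71, 71: 65, 67: 84, 84: 67}  # A<->G, C<->T (byte codes)


@dataclass(frozen=True)
class SubfamilySpec:
    """Activity model and element properties of one TE subfamily."""

    name: str
    mu: float          # activity mean, host-tree time units
    sigma: float       # activity s.d., > 0
    rate: float        # expected insertions per unit time per lineage at peak density 1
    element_length: int = 1000

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")


@dataclass
class SimConfig:
    host_tree: Tree
    subfamilies: list[SubfamilySpec]
    ancestral_genome_length: int = 50_000
    truncation_alpha: float = 1.0   # retained 3' fraction ~ Beta(alpha, beta)
    truncation_beta: float = 3.0
    truncation_floor: int = 50      # minimum retained bp
    p_tsd: float = 0.5
    tsd_len_range: tuple[int, int] = (4, 15)
    subst_rate: float = 0.02        # substitutions / site / time unit
    kappa: float = 2.0              # transition/transversion rate ratio
    cpg_multiplier: float = 10.0
    loss_events: list[tuple[str, str]] = field(default_factory=list)  # (branch, subfamily)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_tsd <= 1:
            raise ValueError("p_tsd must lie in [0,1]")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        names = [s.name for s in self.subfamilies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subfamily names")


@dataclass
class InsertionRecord:
    insertion_id: int
    subfamily: str
    branch: str                 # name of the child node of the branch
    time: float
    strand: str
    tsd: Optional[str]          # duplicated target-site sequence, or None
    parent: Optional[int]       # nesting parent insertion id, or None
    element_ids: tuple[int, ...]
    left_tsd_ids: tuple[int, ...] = ()
    right_tsd_ids: tuple[int, ...] = ()


@dataclass
class TruthRegistry:
    insertions: dict[int, InsertionRecord] = field(default_factory=dict)
    losses: list[tuple[str, str]] = field(default_factory=list)

    def nesting_counts(self) -> dict[tuple[str, str], int]:
        """True (inner subfamily, outer subfamily) nesting counts."""
        counts: dict[tuple[str, str], int] = {}
        for rec in self.insertions.values():
            if rec.parent is not None:
                outer = self.insertions[rec.parent].subfamily
                key = (rec.subfamily, outer)
                counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class _TaxonState:
    cols: list[int]
    bases: list[str]


@dataclass
class SimulatedLocus:
    """One insertion locus: true cross-taxon alignment plus truth states."""

    locus_id: str
    insertion_id: int
    subfamily: str
    orientation: str
    rows: dict[str, str]                  # taxon -> aligned sequence
    element_span: tuple[int, int]         # alignment columns, half-open
    tsd_columns: Optional[tuple[list[int], list[int]]]
    present_taxa: frozenset[str]
    clipped: bool
    intact: bool                          # flanks free of other insertions


class SimResult:
    """Extant genomes, annotations and the truth registry of one simulation."""

    def __init__(
        self,
        config: SimConfig,
        registry: TruthRegistry,
        taxa: dict[str, _TaxonState],
        after: dict[int, list[list[int]]],
        ancestral_ids: list[int],
        owner: dict[int, int],
        masters: Optional[dict[str, str]] = None,
    ):
        self.config = config
        self.registry = registry
        self._taxa = taxa
        self._after = after
        self._ancestral_ids = ancestral_ids
        self._owner = owner  # element column id -> insertion id
        self.masters: dict[str, str] = masters or {}
        self._global_order: Optional[list[int]] = None
        self._global_index: Optional[dict[int, int]] = None
        self._colsets: Optional[dict[str, frozenset[int]]] = None

    @property
    def taxon_names(self) -> list[str]:
        return list(self._taxa)

    def genome(self, taxon: str) -> Sequence:
        st = self._taxa[taxon]
        return Sequence(id=taxon, residues="".join(st.bases))

    def annotations(self, taxon: str) -> list[TECopyAnnotation]:
        """Per-copy fragment intervals; fragments of one copy share fragment_group."""
        st = self._taxa[taxon]
        annos: list[TECopyAnnotation] = []
        run_owner: Optional[int] = None
        run_start = 0
        for pos, col in enumerate(st.cols + [_START]):
            own = self._owner.get(col)
            if own != run_owner:
                if run_owner is not None:
                    rec = self.registry.insertions[run_owner]
                    annos.append(
                        TECopyAnnotation(
                            seq_id=taxon,
                            start=run_start,
                            end=pos,
                            subfamily=rec.subfamily,
                            fragment_group=f"ins{run_owner}",
                            strand=rec.strand,
                        )
                    )
                run_owner, run_start = own, pos
        annos.sort(key=lambda a: (a.seq_id, a.start))
        return annos

    def present_taxa(self, insertion_id: int) -> frozenset[str]:
        if self._colsets is None:
            self._colsets = {
                t: frozenset(st.cols) for t, st in self._taxa.items()
            }
        rec = self.registry.insertions[insertion_id]
        out = set()
        for taxon, cols in self._colsets.items():
            if any(cid in cols for cid in rec.element_ids):
                out.add(taxon)
        return frozenset(out)

    # -- global column order ----------------------------------------------
    def global_order(self) -> list[int]:
        if self._global_order is None:
            order: list[int] = []
            # iterative DFS: a column is followed by the blocks inserted after it
            stack: list[int] = []

            def push_block(block: list[int]) -> None:
                stack.extend(reversed(block))

            for block in reversed(self._after.get(_START, [])):
                push_block(block)
            # interleave: treat ancestral sequence as the outermost block
            stack_final = list(reversed(self._ancestral_ids))
            # process START-attached blocks first (they precede everything)
            pre = []
            while stack:
                col = stack.pop()
                pre.append(col)
                for block in reversed(self._after.get(col, [])):
                    push_block(block)
            order.extend(pre)
            stack = stack_final
            while stack:
                col = stack.pop()
                order.append(col)
                for block in reversed(self._after.get(col, [])):
                    stack.extend(reversed(block))
            self._global_order = order
            self._global_index = {c: i for i, c in enumerate(order)}
        return self._global_order

    def global_index(self) -> dict[int, int]:
        self.global_order()
        assert self._global_index is not None
        return self._global_index


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _branch_intensity(spec: SubfamilySpec, t0: float, t1: float) -> float:
    return spec.rate * (norm.cdf((t1 - spec.mu) / spec.sigma)
                        - norm.cdf((t0 - spec.mu) / spec.sigma))


def _sample_times(spec: SubfamilySpec, t0: float, t1: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    lo = norm.cdf((t0 - spec.mu) / spec.sigma)
    hi = norm.cdf((t1 - spec.mu) / spec.sigma)
    u = rng.uniform(lo, hi, size=n)
    return spec.mu + spec.sigma * norm.ppf(u)


def _substitute(bases: list[str], dt: float, cfg: SimConfig,
                rng: np.random.Generator) -> None:
    """Accumulate substitutions over ``dt`` time units, in place.

    Per-site event counts are Poisson with the CpG context evaluated at the
    start of the interval; intervals are kept short by splitting branches at
    insertion events, so within-interval context changes are negligible.
    """
    if dt <= 0 or not bases or cfg.subst_rate <= 0:
        return
    arr = np.frombuffer("".join(bases).encode(), dtype=np.uint8).copy()
    rates = np.full(arr.shape, cfg.subst_rate)
    if cfg.cpg_multiplier > 1 and len(arr) > 1:
        is_c = arr[:-1] == 67
        is_g = arr[1:] == 71
        cpg_start = np.flatnonzero(is_c & is_g)
        rates[cpg_start] *= cfg.cpg_multiplier
        rates[cpg_start + 1] *= cfg.cpg_multiplier
    n_events = rng.poisson(rates * dt)
    hit_sites = np.flatnonzero(n_events)
    if hit_sites.size == 0:
        return
    p_transition = cfg.kappa / (cfg.kappa + 2.0)
    for site in hit_sites:
        b = int(arr[site])
        if b not in _TRANSITION:  # N or other: left untouched
            continue
        for _ in range(int(n_events[site])):
            if rng.random() < p_transition:
                b = _TRANSITION[b]
            else:
                # one of the two transversion targets, uniformly
                purine = b in (65, 71)
                choices = (67, 84) if purine else (65, 71)
                b = int(choices[rng.integers(2)])
        arr[site] = b
    new = arr.tobytes().decode()
    bases[:] = list(new)


def simulate_history(config: SimConfig) -> SimResult:
    """Run the full generative process; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    L0 = config.ancestral_genome_length
    ancestral = rng.choice(_BASES, size=L0)
    ancestral_bases = ancestral.tobytes().decode()

    masters = {
        s.name: "".join(
            rng.choice(["A", "C", "G", "T"], size=s.element_length)
        )
        for s in config.subfamilies
    }

    next_col = L0
    next_insertion = 0
    registry = TruthRegistry()
    after: dict[int, list[list[int]]] = {}
    owner: dict[int, int] = {}
    taxa: dict[str, _TaxonState] = {}
    loss_by_branch: dict[str, list[str]] = {}
    known_subfams = {s.name for s in config.subfamilies}
    for branch, subfam in config.loss_events:
        if subfam not in known_subfams:
            raise ValueError(f"loss event names unknown subfamily {subfam!r}")
        loss_by_branch.setdefault(branch, []).append(subfam)

    # warn on subfamilies whose activity never overlaps the tree
    node_times: dict[int, float] = {id(config.host_tree.root): 0.0}
    for node in config.host_tree.preorder():
        if node.parent is not None:
            node_times[id(node)] = node_times[id(node.parent)] + (node.length or 0.0)
    for spec in config.subfamilies:
        if spec.rate > 0:
            total = sum(
                _branch_intensity(spec, node_times[id(n.parent)], node_times[id(n)])
                for n in config.host_tree.preorder() if n.parent is not None
            )
            if total < 1e-9:
                warnings.warn(
                    f"subfamily {spec.name}: activity density ~0 on every branch; "
                    "expect zero copies",
                    stacklevel=2,
                )

    def insert(state: _TaxonState, spec: SubfamilySpec, branch: str, time: float) -> None:
        nonlocal next_col, next_insertion
        L = len(state.cols)
        p = int(rng.integers(0, L + 1))
        # nesting test: the insertion point splits two columns owned by the
        # same existing element copy
        parent = None
        if 0 < p < L:
            left_owner = owner.get(state.cols[p - 1])
            if left_owner is not None and left_owner == owner.get(state.cols[p]):
                parent = left_owner
        frac = rng.beta(config.truncation_alpha, config.truncation_beta)
        retained = max(min(spec.element_length, config.truncation_floor),
                       int(round(frac * spec.element_length)))
        elem = masters[spec.name][-retained:]   # 3' end survives
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            elem = reverse_complement(elem)
        tsd_seq: Optional[str] = None
        tsd_len = 0
        if config.p_tsd > 0 and rng.random() < config.p_tsd:
            lo, hi = config.tsd_len_range
            cand = int(rng.integers(lo, hi + 1))
            if p + cand <= L:
                tsd_len = cand
                tsd_seq = "".join(state.bases[p : p + tsd_len])
        insert_idx = p + tsd_len
        elem_ids = list(range(next_col, next_col + len(elem)))
        next_col += len(elem)
        tsd_ids: list[int] = []
        if tsd_seq is not None:
            tsd_ids = list(range(next_col, next_col + tsd_len))
            next_col += tsd_len
        block_ids = elem_ids + tsd_ids
        block_bases = list(elem) + (list(tsd_seq) if tsd_seq else [])
        left_neighbor = state.cols[insert_idx - 1] if insert_idx > 0 else _START
        after.setdefault(left_neighbor, []).append(block_ids)
        state.cols[insert_idx:insert_idx] = block_ids
        state.bases[insert_idx:insert_idx] = block_bases
        for cid in elem_ids:
            owner[cid] = next_insertion
        registry.insertions[next_insertion] = InsertionRecord(
            insertion_id=next_insertion,
            subfamily=spec.name,
            branch=branch,
            time=time,
            strand=strand,
            tsd=tsd_seq,
            parent=parent,
            element_ids=tuple(elem_ids),
            left_tsd_ids=tuple(state.cols[p : p + tsd_len]) if tsd_seq else (),
            right_tsd_ids=tuple(tsd_ids),
        )
        next_insertion += 1

    def evolve_branch(state: _TaxonState, node: TreeNode) -> None:
        t0 = node_times[id(node.parent)]
        t1 = node_times[id(node)]
        branch = node.name or f"node@{t1:g}"
        events: list[tuple[float, SubfamilySpec]] = []
        for spec in config.subfamilies:
            lam = _branch_intensity(spec, t0, t1)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n:
                for t in _sample_times(spec, t0, t1, n, rng):
                    events.append((float(t), spec))
        events.sort(key=lambda e: e[0])
        # substitution is applied in segments between insertions; on branches
        # with very many insertions the segment count is capped (each copy
        # then misses at most one segment's worth of substitution time)
        max_segments = 40
        if len(events) <= max_segments:
            t_prev = t0
            for t_ev, spec in events:
                _substitute(state.bases, t_ev - t_prev, config, rng)
                insert(state, spec, branch, t_ev)
                t_prev = t_ev
            _substitute(state.bases, t1 - t_prev, config, rng)
        else:
            bounds = np.linspace(t0, t1, max_segments + 1)
            ei = 0
            for k in range(max_segments):
                _substitute(state.bases, float(bounds[k + 1] - bounds[k]), config, rng)
                while ei < len(events) and events[ei][0] <= bounds[k + 1]:
                    insert(state, events[ei][1], branch, float(events[ei][0]))
                    ei += 1
        for subfam in loss_by_branch.get(branch, []):
            registry.losses.append((branch, subfam))
            keep_cols, keep_bases = [], []
            for cid, b in zip(state.cols, state.bases):
                own = owner.get(cid)
                if own is not None and registry.insertions[own].subfamily == subfam:
                    continue
                keep_cols.append(cid)
                keep_bases.append(b)
            state.cols, state.bases = keep_cols, keep_bases

    def walk(node: TreeNode, state: _TaxonState) -> None:
        if node.is_leaf:
            taxa[node.name] = state
            return
        for i, child in enumerate(node.children):
            child_state = (
                state if i == len(node.children) - 1
                else _TaxonState(cols=list(state.cols), bases=list(state.bases))
            )
            evolve_branch(child_state, child)
            walk(child, child_state)

    root_state = _TaxonState(
        cols=list(range(L0)), bases=list(ancestral_bases)
    )
    walk(config.host_tree.root, root_state)
    return SimResult(
        config=config,
        registry=registry,
        taxa=taxa,
        after=after,
        ancestral_ids=list(range(L0)),
        owner=owner,
        masters=masters,
    )


# ---------------------------------------------------------------------------
# derived outputs
# ---------------------------------------------------------------------------

def emit_locus_alignments(result: SimResult, flank: int = 750) -> list[SimulatedLocus]:
    """Exact per-insertion cross-taxon alignments with truth presence states.

    Each locus is the insertion's element columns (including any nested
    younger insertions) plus up to ``flank`` bases of flanking sequence on
    each side, counted in a taxon that carries the insertion; loci at
    sequence ends are clipped and flagged.
    """
    order = result.global_order()
    gidx = result.global_index()
    taxon_maps = {
        t: dict(zip(st.cols, st.bases)) for t, st in result._taxa.items()
    }
    loci: list[SimulatedLocus] = []
    own_block: dict[int, set[int]] = {}
    for rec in result.registry.insertions.values():
        own_block[rec.insertion_id] = set(rec.element_ids) | set(rec.right_tsd_ids)

    ancestral = set(result._ancestral_ids)
    for ins_id, rec in sorted(result.registry.insertions.items()):
        present = result.present_taxa(ins_id)
        if not present:
            continue  # lost everywhere: no locus to anchor
        ref = sorted(present)[0]
        ref_map = taxon_maps[ref]
        first = gidx[rec.element_ids[0]]
        last = gidx[rec.element_ids[-1]]
        left_cols: list[int] = []
        got = 0
        i = first - 1
        while i >= 0 and got < flank:
            cid = order[i]
            left_cols.append(cid)
            if cid in ref_map:
                got += 1
            i -= 1
        clipped = got < flank
        left_cols.reverse()
        right_cols: list[int] = []
        got = 0
        i = last + 1
        while i < len(order) and got < flank:
            cid = order[i]
            right_cols.append(cid)
            if cid in ref_map:
                got += 1
            i += 1
        clipped = clipped or got < flank
        window = left_cols + order[first : last + 1] + right_cols
        rows = {
            taxon: "".join(tmap.get(cid, "-") for cid in window)
            for taxon, tmap in taxon_maps.items()
        }
        span = (len(left_cols), len(left_cols) + (last - first + 1))
        tsd_columns = None
        if rec.tsd is not None:
            pos = {cid: k for k, cid in enumerate(window)}
            left_t = [pos[c] for c in rec.left_tsd_ids if c in pos]
            right_t = [pos[c] for c in rec.right_tsd_ids if c in pos]
            if left_t and right_t:
                tsd_columns = (left_t, right_t)
        allowed = ancestral | own_block[ins_id]
        intact = all(cid in allowed for cid in window)
        loci.append(
            SimulatedLocus(
                locus_id=f"locus_ins{ins_id}",
                insertion_id=ins_id,
                subfamily=rec.subfamily,
                orientation=rec.strand,
                rows=rows,
                element_span=span,
                tsd_columns=tsd_columns,
                present_taxa=present,
                clipped=clipped,
                intact=intact,
            )
        )
    return loci


def simulate_survey_reads(
    genome: Sequence, read_len: int = 100, coverage: float = 0.2, seed: int = 0
) -> list[Sequence]:
    """Uniform random-strand reads at the requested fold coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    L = len(genome)
    if L < read_len:
        raise ValueError(f"genome length {L} < read length {read_len}")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(coverage * L / read_len)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    flip = rng.random(n_reads) < 0.5
    reads = []
    for i, (s, rc) in enumerate(zip(starts, flip)):
        sub = genome.residues[s : s + read_len]
        if rc:
            sub = reverse_complement(sub)
        reads.append(Sequence(id=f"{genome.id}_read{i}", residues=sub))
    return reads


def simulate_nesting_counts(
    specs: TypingSequence[SubfamilySpec],
    n_insertions: int,
    seed: int = 0,
) -> dict[tuple[str, str], int]:
    """Mechanistic nesting-count generator for activity-model recovery tests.

    Copies are drawn with Normal(mu, sigma) insertion times (subfamily chosen
    uniformly) and each copy nests into one earlier copy chosen with
    probability proportional to element length — a direct simulation of the
    transposition-in-transposition sampling process, independent of the
    likelihood used to invert it.
    """
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(specs), size=n_insertions)
    times = np.array([
        rng.normal(specs[i].mu, specs[i].sigma) for i in idx
    ])
    order = np.argsort(times)
    counts: dict[tuple[str, str], int] = {}
    weights: list[float] = []
    hosts: list[str] = []
    for k in order:
        spec = specs[int(idx[k])]
        if hosts:
            w = np.array(weights)
            j = rng.choice(len(hosts), p=w / w.sum())
            key = (spec.name, hosts[int(j)])
            counts[key] = counts.get(key, 0) + 1
        hosts.append(spec.name)
        weights.append(float(spec.element_length))
    return counts
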