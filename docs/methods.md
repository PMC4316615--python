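# Methods

This note records the models behind each analysis, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Generative model (simulator)

The simulator plays the biology forward along a rooted, dated host tree.
Time starts at 0 at the root and increases toward the present (larger =
younger); every module shares this convention.

**Insertion process.** Each subfamily *s* has a Gaussian activity period
N(μₛ, σₛ) on the host time axis and a rate parameter rₛ (expected
insertions per unit time per lineage at unit density). On a branch spanning
[t₀, t₁] the number of insertions is Poisson with mean
rₛ·(Φ((t₁−μₛ)/σₛ) − Φ((t₀−μₛ)/σₛ)) and times are drawn from the
truncated normal. A subfamily whose activity window misses every branch
triggers a warning and yields zero copies.

**Integration mechanics.** The insertion site is uniform over the current
genome. A site falling strictly inside an existing copy's element sequence
creates a nesting: the host copy is split into two fragments that keep a
shared fragment-group identifier in the annotation output. Orientation is
uniform. With probability `p_tsd` (default 0.5) the target site of length
drawn from `tsd_len_range` (default 4–15 bp) is duplicated so that
identical direct repeats flank the new element. New copies are 5'-truncated:
the retained 3' fraction is Beta(1, 3) with a 50-bp floor — reverse
transcription of these LINEs initiates at the 3' end and rarely completes,
but no quantitative truncation distribution is established, so both shape
parameters and the floor are configuration options. Copies are never
excised; optional lineage-loss events delete every copy of one subfamily
from one host lineage (an instant purge; gradual per-copy decay is out of
scope).

**Substitution.** A two-parameter model: per-site rate `subst_rate`
(default 0.02/site/time), transition:transversion rate ratio κ (default 2),
and a CpG multiplier (default 10) applied to both positions of every CpG
dinucleotide. Substitutions are applied per branch segment as independent
per-site Poisson event counts with the CpG context evaluated at the segment
start; segments are delimited by insertion events, capped at 40 per branch
(on insertion-dense branches a new copy can miss at most one segment's
substitution time, ≤2.5% of the branch). Within-segment context flips are
ignored; at the default rates this is a second-order effect. There are no
indels outside insertion/TSD events, which keeps all coordinates exact for
the oracles.

**Truth bookkeeping.** Every base ever created carries a globally unique
column identifier. Extant genomes are projections of a global column order,
so the per-locus multi-species alignments the marker module consumes are
exact by construction (no re-alignment step), the truth registry knows each
insertion's branch, time, orientation, TSD and nesting parent, and
per-taxon annotations (with fragment linkage) fall out of a linear scan.
What this means for test interpretation: passing the marker-pipeline checks
shows the scoring logic is correct on structurally clean alignments; it
does not exercise alignment error, assembly gaps, or indel noise, which
real per-locus alignments contain.

## Candidate loci and presence/absence scoring

Candidate loci require `flank` (default 750) bp of TE-free sequence on both
sides; loci at sequence edges are excluded and counted. An optional intron
catalog restricts candidates to loci whose flanks match a catalog sequence
shorter than 1.5 kb, using the same local matcher as copy discovery.

Scoring a locus alignment is deliberately strict. PRESENT requires the
element span ≥90% occupied, subfamily and orientation matching the locus
reference, both flanks ≥50% aligned, and — when the locus defines a TSD —
both TSD spans filled at the same placement. The TSD criterion checks
placement rather than left/right sequence identity: substitutions accumulate
in old TSDs, and demanding exact identity would misclassify genuinely
orthologous old insertions (the criterion applies only where a TSD exists
at all). ABSENT requires a completely empty element span between aligned
flanks. Everything else is AMBIGUOUS with machine-readable reason codes
(`subtype_mismatch`, `orientation_mismatch`, `partial_element`,
`flank_missing`, `missing_data`, `tsd_mismatch`, `deletion_spanning_site`);
an all-gap row is AMBIGUOUS, never an error.

Two markers conflict iff, restricted to taxa where both have definite
calls, their PRESENT sets overlap without nesting. Because the ancestral
state of an insertion character is known (absent), pairwise compatibility
of all markers is equivalent to the existence of a perfect phylogeny, and
the package verifies this constructively.

**Branch test.** For each internal branch the support count is the number
of markers whose PRESENT set equals the clade below it (with at least one
definite ABSENT outside); the two conflict categories are the markers
matching either alternative resolution of the quartet around the branch
(each child clade joined with the branch's sister group). Markers matching
none of the three are reported as unassigned and excluded from n — how
unassignable patterns should enter the test is not established, and
excluding them keeps the three-category null coherent. Λ = 2·Σ kᵢ·ln(kᵢ/(n/3))
with p = χ²(df=2) survival; an exact mode enumerates the multinomial and
sums outcomes at least as extreme *in favour of the focal resolution*
(statistic ≥ observed with the focal count maximal), which reproduces
p = 3⁻ᵏ for clean (k, 0, 0) patterns. Autapomorphies (single-taxon PRESENT)
are tallied separately; they date species-specific activity but support no
internal branch.

## TinT activity model

Nesting extraction trusts fragment linkage: a nesting (i into j) is
recorded when a fragment group of i lies strictly inside the gap between
two same-strand fragments of one j copy and the maximal contained groups
fill the gap to within `gap_tolerance` (default 10 bp; raise it to at least
the maximum TSD length when TSDs are simulated, since the nested copy's own
duplication occupies part of the gap). Only maximal contained groups fill a
gap — a copy nested inside a nested copy is that inner copy's nesting and
is counted when the inner copy's own fragments are processed. Overlapping
but non-contained copies and unexplained gap residue are tallied in a
diagnostics report rather than counted.

The likelihood is a principled reconstruction (the published method's
internals are described elsewhere): an insertion of *i* nests in a *j* copy
with probability proportional to the target space *j* offers (annotated bp;
copy counts via option) times the probability the *i* event postdates the
*j* event, q_ij ∝ bpⱼ·Φ((μᵢ−μⱼ)/√(σᵢ²+σⱼ²)), normalised over hosts per
inserter; rows of the nesting matrix are treated as independent
multinomials. Identifiability: μ of the first subfamily pinned to 0, mean σ
pinned to 1. Optimisation is multi-start (default 10 seeded starts,
Nelder–Mead then Powell polish, log-σ clipped to ±5); the best attained
log-likelihood is reported and never decreases across accepted iterations.
Subfamilies with no nesting evidence in either direction are flagged and
excluded. Known limitation: σ for the extreme oldest/youngest subfamilies
is weakly identified and can collapse toward the clip boundary — the rank
ordering of μ, which is what chronologies read off, is unaffected on
recovery simulations. Central 75/95/99% activity intervals use
z = 1.1503, 1.9600, 2.5758.

## Landscapes

K2P distance d = −½·ln((1−2P−Q)·√(1−2Q)) over columns where both rows have
an unambiguous base, excluding both positions of every CpG dinucleotide in
the ungapped consensus (full exclusion; a partial down-weighting variant is
deliberately not the default, as full exclusion matches the stated
behaviour of the reference masking pipeline most directly). Non-positive
logarithm arguments flag the copy as saturated (d = ∞ sentinel). Copies
contribute their aligned bp (gap/N columns excluded, before CpG exclusion)
to bin ⌊100·d⌋ of their subfamily's group; copies at d ≥ 50% and saturated
copies are discarded and counted. "Ongoing activity" is flagged for a group
with more than 100,000 bp in the [0, 1%) bin — "no divergence from
consensus" is operationalised as the first bin.

## Survey quantification

Reads are matched strand-aware against each library consensus with the
shared seed-and-extend matcher; per read, best-scoring non-overlapping hits
(option: single best) are kept, hits shorter than 30 bp dropped, and
matched bp accumulated per subfamily (read counts via option). The identity
floor is 0.7 so that old, diverged copies remain detectable. Calibration
divides a reference species' assembly bp by its survey bp per subfamily;
estimates for other libraries are cₛ·survey_bpₛ. The detection biases
(edge losses at the 30-bp floor, extension overrun, divergence-dependent
sensitivity) cancel in the ratio exactly to the extent they match the
calibration species — cross-species transfer of coefficients is supported
but the estimates are rough by construction. Subfamilies with zero survey
bp in the calibration library are flagged uncalibratable and omitted from
estimates with a warning.

## Consensus building

Copy discovery is exact-11-mer seeding with ungapped X-drop extension
(mismatch −2, drop 20) and greedy best-score non-overlap resolution;
optional gapped refinement re-scores candidate spans with edlib. Up to 50
top copies are extracted with up to 1,000 bp of flank and multiply aligned
(mafft G-INS-i; the fast progressive mode opens spurious gaps that corrupt
majority calling, and copy sets are small enough for the accurate mode).
The consensus is per-column majority with 'N' as missing, gaps winning only
on strict majority, and base ties broken alphabetically (A<C<G<T). The seed
core is grown over flank windows whose mean pairwise column identity stays
≥ θ = 0.6 (window 50 columns): conserved flanks are element sequence shared
by all copies, variable flanks are the copies' unrelated genomic
neighbourhoods. A terminus is complete iff the adjacent outside window's
mean identity is < θ; alignment columns too sparse to stack count as
maximally variable. θ and the window quantify "highly variable flanks",
which has no established numeric value; both are exposed. The iterative
loop (≤10 rounds, +500 bp flank per incomplete end) re-queries with the
current consensus. Clustering is greedy-centroid at 95% identity,
longest-first (ties lexicographic by id), identity defined as matches over
global-alignment length so that gaps count against identity — the semantics
common to the clustering tools this threshold convention comes from; merged
consensi are rebuilt by majority rule over members.

## Reconciliation and retention

LCA mapping, duplication labelling and the lineage count follow the
standard gene-tree/species-tree convention: a node mapping to the same host
node as one of its children is a duplication; speciation nodes at the focal
host node are a single copy co-diverging with its hosts and are not
additional lineages. A virtual origin edge above the TE root (mapped to the
host root) lets outgroup-rooted TE trees contribute their crossing edge
into the ingroup. The packaged amniote CR1 fixture is a synthetic
class-level rendering of the published subfamily tree (one tip per group ×
host class); its seven-lineage count at Amniota depends on the
mammal-bearing groups (B, C, G) being interleaved among reptile-restricted
ones so every inter-group node maps to Amniota — see
`retrochron/fixtures.py` for the full statement of this dependency.

Dollo retention assumes a single gain at the stated origin and unlimited
losses: a group is retained on every branch from the origin to each carrier
taxon and lost once on the stem of each maximal carrier-free clade, which
is the unique minimum-loss placement (verified against exhaustive
enumeration on the amniote host tree).

## Problem sizes and determinism

The reference scenarios use ancestral genomes of 20–200 kb, two to six
subfamilies, four-taxon host trees, ~600 nestings for chronology fitting,
and 0.2× coverage of 100-bp reads — sizes at which every stage's behaviour
(Poisson copy counts, binomial read sampling, multinomial nesting counts)
is already in its asymptotic regime while full studies run in minutes. The
survey scenario uses ≥250 kb of content per subfamily so that read-sampling
noise (relative s.d. ≈ √(read_len/(coverage·bp))) stays well inside the 20%
comparison band. Every randomised operation takes an explicit integer seed;
identical seeds give byte-identical outputs, and `scripts/acceptance.py`
derives all of its sub-seeds from its single `--seed` argument.
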