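# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `codiv`. It is written for users who need to know exactly
what the pipeline computes and what the synthetic-data tests do and do not
demonstrate.

## OTU assembly

**Trimming and dereplication.** Reads are truncated to `trim_length`
(default 275 bp, matching the amplicon design the pipeline targets); shorter
reads are discarded with a logged count. Identical reads are collapsed into
unique haplotypes carrying abundances and per-locale counts; uniques are
ordered by (abundance descending, sequence lexicographic), which makes every
downstream step invariant to the input order of reads.

**Pairwise identity.** Identity between two sequences is computed from an
optimal global (Needleman–Wunsch/Gotoh) alignment scored match +1,
mismatch −1, internal gap open −5 / extend −1, and terminal gaps −0.5 per
column (open and extend). Identity is matching columns divided by alignment
columns, excluding terminal-gap columns; `N` never matches. Terminal gaps are
*cheap but not free* by design: with fully free end gaps the optimal
alignment of two unrelated equal-length sequences degenerates to a tiny
staggered overlap whose non-terminal core is nearly 100% identical, which
would merge unrelated OTUs at any threshold. A small end-gap penalty forces
full-overlap alignments for unrelated pairs (identity ≈ 25%) while keeping
genuine indel overhangs inexpensive. Alignments are computed with Biopython's
`PairwiseAligner`; an independent Gotoh dynamic program in the test suite
verifies the optimal scores.

**Clustering.** Greedy abundance-sorted centroid clustering: each unique
joins the existing centroid of maximum identity if that identity reaches the
threshold (default 0.97; ties go to the lowest OTU id), otherwise it founds a
new OTU — unless the chimera screen flags it. Exhaustive query-vs-centroid
comparison is used rather than heuristic k-mer search; at the scale this
package targets (thousands of reads, hundreds of uniques) this is fast and
fully deterministic. By construction all centroids are pairwise below the
threshold and every member is within the threshold of its centroid.

**Chimera screen.** A single-crossover model: for every ordered centroid pair
and breakpoint on a 5 bp grid (each segment ≥ 50 bp), the query prefix is
compared ungapped to one parent and the suffix to the other. The query is
discarded as chimeric when the best spliced identity reaches the clustering
threshold and beats the best single-centroid identity by ≥ 0.01. The
false-positive rate on unrelated random queries is below 1% (tested).

**Comparative filter.** An OTU enters the comparative set when it has at
least `min_otu_size` (10) sequences in total and at least `min_per_region`
(3) on each side of the barrier. Exactly two regions are required.

## Alignment

Per-OTU multiple alignments are built center-star: the most abundant
haplotype (lexicographic tie-break) is the center, every other haplotype is
pairwise-aligned to it with the scoring above, and pairwise alignments merge
under "once a gap, always a gap" with left-justified insertion slots.
Stripping gaps from any row reproduces its input sequence exactly (tested as
a property). For ~275 bp amplicons at within-OTU divergences ≤ 3% this is
adequate; externally produced aligned FASTA (e.g. from MAFFT) is accepted as
a first-class alternative and all downstream statistics use pairwise-valid
sites, limiting sensitivity to aligner choice.

## Per-OTU statistics

**Gap handling.** All pairwise quantities use pairwise deletion: columns with
a gap or `N` in either sequence of a pair are excluded and the remaining
valid-site count is recorded per pair. Segregating sites *S* count columns
with ≥ 2 distinct non-gap, non-`N` states; θ_W uses L_eff = number of columns
that are not entirely gaps. A pair sharing no valid sites disqualifies the
OTU from sequence statistics.

**Weighted computation.** Statistics accept a per-row multiplicity vector so
that a 2,500-read OTU with 80 distinct haplotypes is processed on the 80×80
haplotype matrix. Identical-copy pairs contribute zero differences; weighted
and expanded computations agree exactly (tested).

**Tajima's D.** D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ as functions of n. D is reported *missing*
(never zero) when n < 4 or S = 0. Significance defaults to the classical
rescaled-beta null: D is mapped onto [D_min, D_max] (the parity-dependent
closed forms in terms of n and a₁) and tested two-tailed against a Beta
distribution whose shapes give mean 0 and variance 1 on that interval. A
simulation mode draws Kingman genealogies at the observed n, places the
observed S mutations multinomially on branches by length (infinite sites:
a mutation on a branch subtending i tips adds i(n−i) pairwise differences),
and returns the empirical two-tailed rank with +1 smoothing; it is the
automatic fallback when the beta shapes degenerate.

*Known limitation:* the beta null assumes Var(D) = 1, but the simulated
neutral null of D has variance ≈ 0.78–0.93 for n ∈ [10, 50] (confirmed with
two independent simulators, including msprime with Poisson mutations).
Two-tailed beta and simulation p-values can therefore differ by up to ~0.1
at moderate |D|; they agree closely (≤ 0.02) in the deep tails where
significance at α = 0.05 is actually decided. The beta mode is the default
because it is the field's standard report; users needing calibrated
mid-range p-values should use the simulation mode.

**G_ST.** Haplotypes are alleles. The default estimator applies the
small-sample corrections: unbiased within-locale diversity
h_p = n_p/(n_p−1)·(1 − Σp²), H_S the unweighted mean of h_p, total diversity
from unweighted mean allele frequencies plus H_S/(ñP) with ñ the harmonic
mean locale size; the uncorrected form is available via a flag. Significance
permutes individuals among locales preserving locale sizes. A monomorphic
OTU reports G_ST as missing.

**AMOVA.** Squared pairwise distances (raw differences by default, K2P via
config) are decomposed into among-region, among-locale-within-region and
within-locale sums of squares; SSD additivity is exact by construction.
Variance components use the standard unequal-size coefficients n′, n″, n‴;
Φ_CT = σ²_a/σ²_tot, Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_tot.
Permutation schemes: Φ_ST shuffles individuals among locales ignoring
regions; Φ_SC shuffles individuals among locales within their region; Φ_CT
reassigns whole locales to regions preserving region sizes. All permutation
p-values use (1 + #{perm ≥ obs})/(B + 1) — never zero, slightly conservative.
With five locales the Φ_CT permutation space has only C(5,2) = 10 distinct
assignments, so its attainable p-value floor is ≈ 0.10: Φ_CT cannot reach
significance at α = 0.05 under this sampling design, and its calibration is
assessed only as "not anticonservative".

**Trees and GSI.** Neighbor joining on K2P haplotype distances with
deterministic tie-breaking (smallest index pair), negative branch lengths
clamped to zero with the deficit moved to the sister branch, and the final
three clusters joined at an unresolved root; the tree is midpoint-rooted for
GSI. Identical haplotypes are expanded into zero-length binary caterpillars
so the genealogy is individual-level; caterpillar positions are filled in
seeded random order so the arrangement is region-agnostic (a deterministic
fill would cluster same-region copies and inflate GSI). The GSI of a group is
(gs − gs_min)/(gs_max − gs_min) where gs = k/Σ(d_u − 2) over the internal
nodes of the group's minimal connecting subtree, gs_max = k/(k−1)
(monophyly) and gs_min uses all internal nodes (maximal dispersal); values
are clipped to [0, 1] (a group spanning a root-adjacent leaf can otherwise
nominally exceed the monophyly anchor). GSI is topology-only (branch-length
invariance is tested). K2P saturation (non-positive log argument) flags the
OTU and skips tree-based statistics. External newick genealogies (e.g. ML
trees) can be supplied in place of NJ.

**Mantel.** Genetic distance between locales is the mean K2P distance over
individual cross-locale pairs; geographic distance is great-circle
(haversine, R = 6371 km) from locale coordinates, or a user matrix taken
verbatim. Pearson correlation of upper triangles, one-tailed (isolation by
distance predicts positive r), null by joint row/column permutation.
Undefined for fewer than three locales.

## Community synthesis

Significance uses strict p < α (default α = 0.05) with no multiple-testing
correction across OTUs (matching standard practice for this analysis;
per-OTU p-values are emitted so users can apply their own). Each test's
total counts only OTUs where that test was computable; exclusion reasons are
logged per OTU in the `notes` column. The chi-squared goodness-of-fit
compares the observed significant count against α·N with
χ² = (O−E₁)²/E₁ + ((N−O)−E₂)²/E₂, df = 1. Rarefaction uses the
hypergeometric closed form E[S_m] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)). Group
aggregates report the median Tajima's D and mean π/θ_W/G_ST per annotation
group (median = central element or mean of the central pair).

## The synthetic-data generator

The simulator emulates the study conditions: five demes (two west, three
east of a barrier; one eastern deme with 5× sampling effort), ~275 bp
haplotypes, per-OTU totals from a log-series truncated to [14, 2507] with
p = 0.9965 (median ≈ 55, matching the observed community's median OTU size
of 54; the observed mean of 225 is driven by two extreme OTUs and is not
simultaneously matchable by a log-series), and a mixture of
barrier-structured and panmictic OTUs (default half and half).

Time is scaled so a lineage pair within a deme coalesces at rate 1; τ (the
region split time) and migration rates are in these units. Genealogies come
from msprime (demes as populations, within-region migration m_within,
cross-barrier migration m_between, merge into one panmictic ancestral pool
at τ); mutations are dropped on the tree directly — Poisson(θ/2 × branch
length) per branch, finite-sites Jukes–Cantor on a uniform random ancestral
sequence — so external genealogies can be mutated too. Finite sites (rather
than infinite) deliberately exercises the K2P saturation handling; at
θ/L ≈ 0.01 the repeat-mutation bias is negligible (π and θ_W means over
1,000 replicates sit within 3 Monte-Carlo SE of θ/L; tested).

Community defaults are θ = 3, τ = 1, m_within = 1, m_between = 0. The
rationale: a comparative OTU must *span* the barrier as a single 97% cluster,
which bounds cross-barrier divergence at roughly θ(τ+1) ≲ 8 differences per
275 bp; θ = 3, τ = 1 gives within-OTU π ≈ 0.01–0.02, the range observed in
the real community, while leaving the barrier signal detectable. Deeper
splits (e.g. τ = 10, θ = 5, used in the power tests, which run per-OTU
without re-clustering) make the two sides ~20% divergent — such an OTU is
split by the clustering threshold itself, which is a real behavior of
threshold-based OTU assembly worth knowing about: power results at deep τ do
not transfer to the full pipeline, where deeply structured taxa surface as
region-private OTU pairs that the comparative filter removes.

What passing the synthetic tests does **not** show about real data: the
simulator has no sequencing error, no chimera formation, no selection or
recombination, no taxonomic mixture of mutation rates, and reads sampled
uniformly within demes — so calibration results certify the statistics and
their permutation machinery, not robustness to platform artifacts.

## Calibration summary (measured by the test suite and acceptance script)

On 400 fully panmictic simulated OTUs (B = 199, α = 0.05), the rejection
rates of Φ_ST, Φ_SC, G_ST, GSI (both regions) and Mantel fall inside the
exact 95% binomial interval around 0.05; Φ_CT rejects nothing (attainable
p-floor ≈ 0.10, see above). Under a clean barrier (τ = 10, m_between = 0,
θ = 5, 10 sequences per region), Φ_ST and both GSI tests are significant in
≥ 90% of OTUs at B = 199. Permutation tests on small-integer difference
matrices carry ties, so slight conservatism (rates a little below α) is
expected and observed.

## Numerical and engineering choices

* All randomness flows from one config seed through fixed per-OTU,
  per-statistic stream ids (`default_rng([seed, otu_index, stream])`), so
  reruns are byte-identical and stage-by-stage execution equals `run-all`.
* Distances, SSDs and diversity statistics are computed with vectorized
  indicator-matrix products; AMOVA permutations operate on haplotype count
  vectors (O(P·H²) per permutation).
* Degenerate inputs are reported as missing with a reason, never silently
  zero: D (n < 4 or S = 0), G_ST (monomorphic), Φ statistics (zero total
  variance), GSI (fewer than 3 haplotypes, degenerate normalization, K2P
  saturation), Mantel (fewer than 3 locales, constant matrix).
* The per-locale clustering mode supports the taxonomic-survey side of the
  workflow (rarefaction curves per locale); the global mode feeds the
  comparative analysis. Month filtering is a config switch applied to reads
  before clustering.
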