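# Methods

This note documents the models, conventions and numerical choices behind
aflp-delimit, and what the synthetic data do and do not establish.

## Scoring model

AFLP markers are dominant: a fragment of a given size is either amplified
(band present) or not, and heterozygotes are indistinguishable from
dominant homozygotes. The pipeline starts from size-called peak lists and
never sees chromatograms; baseline correction and size calling against the
internal ladder are upstream of our input contract.

**Binning.** Bins are half-open intervals `[left, left + w)` of width
`w = 0.5` bp anchored at the window start (default 100 bp), so a peak of
size `s` maps to bin `floor((s - start)/w)`. Anchoring is a convention —
only the width is scientifically meaningful — but fixing it makes scoring a
deterministic function of the input. When one sample has several peaks in a
bin, the maximum intensity is kept. Raw-peak filters (window 100–500 bp
half-open, intensity ≥ 30 RFU, width ≤ 1.5 bp where a width is reported)
run before binning; peaks without a width field are not width-filtered,
since many exports omit it.

**Normalization and calling.** Samples differ in total signal for
uninteresting reasons (loading, injection), so each sample is rescaled to
the grand mean of per-sample totals ("sum of signal" normalization, per
channel). Calls are then made per bin against the maximum normalized
intensity *M* in that bin over all samples: ratio < 0.10 → 0,
0.10 ≤ ratio ≤ 0.20 → ?, ratio > 0.20 → 1. Both boundary ratios fall in the
ambiguous class; this is the conservative choice and makes the later
"remove bins with any 10–20% peak" filter coincide exactly with "remove
bins containing a ? call". Because calls depend only on within-bin ratios,
the pipeline is invariant to any per-sample rescaling of the raw signal
(property-tested). Channels are scored independently and concatenated;
bins are labelled `channel:left-edge` so labels never collide.

## Replicate error model and filter

The replicate difference rate between two profiles is the fraction of
*comparable* bins — both calls determinate — at which one is scored 1 and
the other 0. Ambiguous calls are excluded from numerator and denominator
(pairwise deletion), the same convention the p-distance uses; groups with
more than two replicates contribute all within-group pairs. Replication
depth (extraction / digestion–ligation / preamp-only) is carried as
metadata and summarized per level, so the analysis can check that deeper
replication does not add error — as expected when discordance arises in
scoring, not chemistry.

The error filter is a fixed two-step sequence: (1) delete every bin with
any ambiguous call; (2) delete every remaining bin scored present in one
replicate and absent in another replicate of any sample. The order matters
for the per-step attribution recorded in the `FilterTrace` (a bin failing
both criteria is charged to step 1); the retained set is the same either
way, and is invariant under sample and bin reordering. After both steps
every replicate pair agrees at every bin by construction — the acceptance
suite asserts a measured rate of exactly 0.0.

## Distances and NeighborNet

p-distances on three-state profiles use pairwise-complete deletion; a pair
with zero comparable bins has no defined distance and is an error rather
than a silent zero. With no missing data the p-distance equals the Hamming
fraction (tested as a closed form).

The split network is computed in two stages, both authored here:

1. **Circular ordering** by the NeighborNet agglomeration. Active nodes
   are kept in chains of one or two. Each round selects a pair of clusters
   by the neighbor-joining-style criterion
   `Q(A,B) = (m-2) D(A,B) - Σ_C D(A,C) - Σ_C D(B,C)` on cluster-averaged
   distances, then selects the node pair inside them by the same criterion
   with the two chosen clusters broken into singletons. Selected nodes are
   linked; whenever a node would acquire two neighbors, the three chained
   nodes `(a, b, c)` are replaced by two nodes `u, v` with the linear
   reductions `d(u,z) = (2 d(a,z) + d(b,z))/3`,
   `d(v,z) = (2 d(c,z) + d(b,z))/3`,
   `d(u,v) = (d(a,b) + d(a,c) + d(b,c))/3`. When three or fewer nodes
   remain they close into a cycle and the reduction history is expanded in
   reverse. Ties are broken by the lexicographically smallest taxon label
   under each node, making orderings reproducible.
2. **Split weights** by non-negative least squares over all `n(n-1)/2`
   interval splits of the ordering, solved with the active-set NNLS solver
   (scipy). At this package's problem sizes (tens of profiles) the exact
   solver is comfortable; the design matrix is ~O(n² × n²). Splits with
   weight below `weight_epsilon = 1e-9` are numerical zeros from the
   active-set solver and are pruned. The fit statistic is the percent of
   squared distance explained.

Correctness is checked against two oracles: on additive (tree) metrics the
split system must equal the neighbor-joining tree's splits with weights
equal to branch lengths (NJ provided independently by scikit-bio), and on
distances forward-constructed from random circular split systems the
generating weights must be recovered to 1e-6. Both hold across seeded
batches in the acceptance suite.

**Group extraction.** The source analysis reads clusters off the network
figure by eye; here delineation is explicit: single-linkage agglomeration
on the p-distance matrix cut at a requested `k` (or distance threshold).
Single linkage was chosen because it respects the connectivity structure
of the network; taxa are fed in label order so ties resolve
deterministically. Other linkages are out of scope.

## Sequence track

**Simple indel coding.** Each positionally distinct internal gap (maximal
`-` run with identical start and end) becomes one binary character: 1 for
taxa bearing exactly that gap, 0 for taxa with residues (or a
non-containing gap) across the span, ? for taxa whose longer gap strictly
contains it. Leading and trailing gap runs are missing data, not
deletions: they are never coded and render any span they cover missing.
Re-coding the coded output is a no-op (tested).

**Character accounting.** A column is variable when it shows ≥ 2 distinct
determinate states and parsimony-informative when ≥ 2 states are each
borne by ≥ 2 taxa. Ambiguity codes, `?`, `N` and gaps never count as
states for these tallies (gaps in nucleotide columns are missing for
counting and parsimony — the companion convention to simple indel coding;
the indel signal lives in the binary characters). Counts are available for
any taxon subset (e.g. outgroups excluded) and with or without the indel
block, since published tallies are not always explicit about either.

**Parsimony.** Tree length is the minimum number of unordered state
changes: the classic two-set recursion on binary trees, and unit-cost
Sankoff dynamic programming on multifurcating ones (the two agree on
binary trees; both are oracle-tested against brute-force enumeration of
internal-state assignments). IUPAC ambiguity codes enter as polymorphic
state sets; missing cells as the full set. The exact search is stepwise
branch and bound — the induced-subtree length never exceeds any
completion's length, so partial trees longer than the incumbent are pruned
— and returns *all* minimal topologies (verified exhaustively at 6–7 taxa;
refused above 14 taxa). The heuristic is 10 random-addition starts with
nearest-neighbor-interchange hill climbing plus a plateau sweep; it is not
a TBR implementation and carries no optimality guarantee, which is why
exactness claims always rest on the branch-and-bound searcher. Reported
trees have branches collapsed whose minimum length is zero, i.e. whose
contraction leaves the Sankoff length unchanged. Bootstrap support
resamples nucleotide and indel characters jointly with replacement,
re-runs the search per replicate (saving at most 1000 trees), and counts a
clade when it appears in the replicate's strict consensus.

## Synthetic data: what it emulates and what it does not

The generator encodes the study conditions the pipeline is built for:
3 clusters, 2 primer-pair channels with a pool of 500 fragments each
(drawn uniformly on 100–500 bp with 0.6 bp minimum spacing), base fragment
presence 0.55, between-cluster divergence 0.30 (per-fragment archetype
flips), and within-cluster rate 0.01 — the selfing regime where
within-cluster diversity is an order of magnitude below divergence.
Intensities are log-normal (`ln` mean 5.0, sd 0.7, median ≈ 150 RFU) with
a per-sample × fragment amplification factor (CV 0.6) that is shared
between a sample's replicates: it widens within-bin intensity ratios and
is the source of ambiguous calls, without contributing replicate error.

Replicates share the true fragment complement — chemistry is faithful —
and differ only in measurement: per-replicate size jitter (Normal,
sd 0.04 bp) that flips fragments across 0.5 bp bin edges, and intensity
jitter (log-normal, CV 0.25) with a detection ramp between 0.7× and 2.2×
the 30 RFU threshold that drops weak peaks in and out of the scored set.
The jitter sd is the calibration knob: `expected_replicate_difference`
(a Monte-Carlo estimator over fresh simulations) was used to set it so
the post-scoring replicate difference rate lands inside the empirically
observed 6–17% band, and the defaults were then frozen. At these defaults
a run scores ~1050 bins across both channels, retains ~200–230 after the
two-step filter, and shows mean replicate difference ≈ 11% — the scale of
a real two-primer-pair AFLP study of this kind. Increasing the size
jitter increases the rate monotonically (tested), which is the bin-edge
mechanism in isolation.

What passing on these data shows: the scoring rules, filter semantics,
distance/network algebra and cluster extraction are correct, and the
pipeline recovers known structure under realistic measurement noise. What
it does not show: robustness to size-calling drift between runs, adaptive
(non-fixed) vendor binning, comigrating non-homologous fragments,
chemistry-level failures that change the true fragment complement, or any
within-cluster population structure — none of which the generator
emulates (a chemistry-error mode is deliberately absent because the noise
model encodes the conclusion that replicate discordance is a scoring
artifact).

The sequence simulator evolves sites down a given tree under
Jukes–Cantor substitution probabilities with Poisson-arriving,
geometric-length deletion events inherited along lineages; columns are
preserved, so the emitted matrix is an alignment by construction.
Insertions are not modelled — column-wise their coded effect mirrors
deletions — and indel placement is uniform, not hotspot-clustered.

## Degenerate inputs and edge conventions

Empty call matrices (all bins filtered) remain valid objects; a sample
with zero total signal is an error at normalization (it cannot be
rescaled); a taxon pair with no comparable characters is an error at
distance time; `n ≤ 3` taxa have a single circular ordering; all-zero
distances yield an empty split list. Exact search below 4 taxa and
bootstrap with zero replicates are refused. Agglomeration and search ties
resolve by label order or seeded randomness, so every result in the
package is reproducible from (input, config, seed).
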