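# Methods

This note documents the models and procedures implemented in
`paleoloss`, the assumptions behind them, the parameters that matter, and
what the synthetic-data tests do and do not demonstrate.

## The inference problem

A sedaDNA metabarcoding record is a set of dated sediment samples from
several lake cores, each yielding read counts over amplicon sequence
variants (ASVs). Three confounders stand between such a record and a
claim that a plant taxon went extinct:

1. **Artefacts.** Once the reference-matching threshold is lowered to 90%
   identity (necessary to see taxa missing from databases), chimeras and
   PCR/sequencing errors enter the table.
2. **Detection flicker.** Occupancy series from sparse records show taxa
   disappearing and reappearing constantly; an absence run is weak
   evidence on its own, and the evidence gets mechanically weaker toward
   the present because fewer slices remain for a reappearance.
3. **Database coverage.** A taxon can look "unknown and lost" simply
   because the reference database does not cover it.

Each confounder gets its own explicit counter: co-occurrence community
validation for (1), the reappearance-delay null for (2), and the
coverage null for (3).

## Community validation and collapsing

Real taxa participate in plant communities and therefore co-occur with
other members of those communities across samples; artefacts do not.
We compute all-pairs Spearman correlations on per-sample counts, apply
the Holm step-down correction over the full family of unordered pairs,
and connect pairs with ρ > 0.4 and adjusted p < 0.05. The published
workflow this mirrors states only the positive-correlation threshold;
we additionally require the Holm-adjusted significance, since computing
the adjustment without using it would be pointless. Both orderings of
threshold and adjustment give the same edge set under this AND rule.

Communities are found by Louvain modularity maximisation on the
unweighted edge set (resolution 1). Louvain is a greedy heuristic, so we
run eight seeded restarts and keep the highest-modularity partition;
this makes the result deterministic given the seed and, on every small
graph in our fixture suite (≤ 8 nodes), reproduces the exhaustive-search
maximum. Communities with fewer than five ASVs are not reported;
their members are treated as unvalidated and discarded from the taxon
set (they are retained in the partition object for diagnostics).

Collapsing within a reported community: dbASVs (100% identity) with
identical assigned names merge into one dbtaxon; a non-dbASV merges into
a dbtaxon when their names agree at the coarser of the two assignment
ranks (a family-rank "Salicaceae" non-dbASV joins a "Salix" dbtaxon of
family Salicaceae); remaining non-dbASVs with identical names merge into
one non-dbtaxon. Ties between equally matching dbtaxa are broken by the
candidate's best member identity, then lexicographically, and logged.
This collapse is deliberately conservative: a genuinely extinct taxon
whose co-occurrence pattern tracks a surviving relative with the same
coarse name will be absorbed into it and missed.

## Replicate QC

A replicate is removed when its total reads fall below 100 **and** it
contains fewer than three distinct ASVs. The published rule couples
these conditions with "and/or" and a visual ordination check; we resolve
it as the conjunction, preceded by a purely numeric divergence flag
(Bray–Curtis distance of the replicate to the leave-one-out centroid of
its sample > 0.9) that substitutes for the visual check. The flag is
diagnostic — removal is decided by the count rule alone — so the QC is
reproducible without human judgement. Samples losing all replicates are
excluded downstream with a warning. The ASV filter (identity ≥ 90%,
≥ 10 samples, ≥ 100 total reads) applies to the merged multi-core table
and is idempotent.

## Time slices and balanced resampling

Fourteen half-open 2000-yr bins cover 28,000–0 cal yr BP; ages map to
bins as [lower, upper), the oldest bound included, so every age has
exactly one slice. Because cores differ in sampling density and depth,
presence/absence is only comparable across slices after balancing. Per
iteration and slice we draw, without replacement: the min-over-slices
number of cores; within each drawn core the min-over-(slice, core)
number of samples; and within each drawn sample a rarefaction of its
reads to the global minimum sample depth, as one multivariate
hypergeometric draw over the taxon count vector. The total resampled
read count is then identical across slices within an iteration.
Presence is ≥ 1 rarefied read of any member ASV. The published record
used a three-step balancing script whose details are in a supplement we
reconstruct: min-across-slices draws without replacement are the
standard rarefaction semantics and conserve counts. Balancing is per
slice; zero-read samples are dropped from the design; rarefaction draws
are independent across iterations (hypergeometric, not nested
permutations), which is what the iteration bands are meant to average
over.

## Reappearance-delay null and loss estimates

For a disappearance at slice *t* (present at *t*, absent at *t*+1), the
delay *d* counts consecutive absent slices before the next presence;
events with no reappearance through the modern slice are censored. The
three reference slices with midpoints ~25, ~23 and ~21 kyr BP leave at
least nine later slices for reappearance; pooling their events per
iteration gives the empirical survival function S(h) = P(d > h),
censored events exceeding every horizon. We use the full survival
function rather than only the median delay because the comparison is
horizon-specific. For a slice with *r* reappearance opportunities
(slices *t*+2 … modern), expected loss is S(min(r, 9)) and observed loss
is the fraction of that slice's events that are censored; net loss is
their difference in percentage points, and confidence is the fraction
of iterations with positive net. Slices with no events in any valid
iteration report net 0 at confidence 0.5 so downstream aggregation stays
defined. For early slices (*r* > 9) the horizon cap makes the expected
value an overestimate of the truly comparable quantity, biasing net loss
down — the estimator is conservative there, and correspondingly the very
oldest slices cannot produce calls. At the final transition (*r* = 0)
every event is censored by construction and S(0) = 1 forces net 0.

Rates are extinctions per million species-years, E/(S·T); reported to
one decimal (two for the megafauna genus-level comparison, matching the
precision its source uses).

## Coverage null, refugium likelihood, bounds

The gain/loss schedule (taxa gained/lost between consecutive slices of
the median occupancy, split db/non-db) is replayed over a species pool
in which each species carries a covered/uncovered flag at the database
coverage fraction (default 0.70). Each iteration starts from the oldest
slice's richness drawn uniformly, then applies the *total* gains and
losses per transition by uniform draws — random attribution of
covered/uncovered, because the null's question is precisely whether
coverage alone explains the observed db/non-db split of losses; the
published worked example is internally inconsistent on class-matched
counts, and imposing the observed split on the simulation would beg the
question. Previously lost species may re-enter (reappearance). The
covered fraction among simulated modern-absent taxa gives the expected
number of lost non-dbtaxa under pure coverage effects (rounded half away
from zero); observed minus expected, floored at zero, is the minimum
number of potential extinctions. The upper bound subtracts the expected
refugium count: for each lost non-dbtaxon matching a global database,
the species overlap at family level between the match region and the
study region (lists capped at 100 by seeded subsampling; denominator is
the match-region list) estimates its outside-survival likelihood, and
round(n_matched × mean likelihood) taxa are deducted.

## Traits, turnover, drivers

SCBD follows the standard sum-of-squares decomposition: the taxon ×
slice abundance matrix is converted to per-slice relative abundances,
square-root transformed (Hellinger), each taxon centred on its own mean
across slices, and a taxon's score is its share of the total sum of
squares (scores sum to 1; a zero-variance table returns the uniform
vector). Turnover between consecutive slices is the replacement
component of presence/absence dissimilarity, min(b,c)/(a+min(b,c))
(Simpson/Baselga form; the Podani/Carvalho form 2·min(b,c)/(a+b+c) is
available via a parameter — the published analysis names only
"replacement rate" without the decomposition family, and the Baselga
form is the more common default). Group contrasts use the two-sided
Mann–Whitney rank-sum (mid-ranks, asymptotic with tie correction) or
Welch's t, with Bonferroni correction for multi-group families;
functional types follow the standard grouping (Poaceae, Juncaceae,
Cyperaceae as graminoids; other herbs as forbs; shrubs; trees), and
family loss proportions consider only families with at least five
non-dbtaxa. Cophenetic distances are tip-to-tip path lengths from a
Newick tree. Driver screens fit one binomial GLM per covariate on the
iteration × slice indicator of positive net loss, reporting the
likelihood-ratio χ² against the intercept-only model; vegetation
turnover enters lagged by one slice. Perfect separation is caught and
the fit rescued with an L2 penalty, flagged in the output.

## The synthetic-data generator

`synthdata.generate_record` emulates the structure of the target record
class: by default 8 cores × 63 samples (504 samples) with uniform dated
depths over 28 kyr (draws leaving a slice empty are rejected), 360 true
taxa in 10 planted communities, 70% database coverage (covered taxa
appear as 100%-identity ASVs, uncovered as 90–99%), ~10% of taxa carry a
second, family-rank non-db ASV, plus 300 independent low-prevalence
noise ASVs. Counts are zero-truncated negative binomial (dispersion 2)
with a mean-normalised lognormal per-taxon abundance spectrum (σ = 1)
around a mean read depth of 10,000 per sample.

Co-occurrence is induced by a shared latent: in a sample whose slice a
community occupies, the community is "on" with probability 0.6; member
ASVs are then detected with probability `detection_prob ×` a per-taxon
detectability drawn from Beta(5, 2). The shared latent produces the
positive rank correlations the network stage thresholds; the Beta spread
makes common taxa reliably detected while a rare tail flickers in and
out of the record, which is what gives the reappearance null its events.
The Beta(5, 2) default reflects that community-validated taxa in real
records of this kind are mostly well-detected (their multi-ASV taxa
co-cluster), while `detection_beta=None` gives homogeneous detection for
clean-signal experiments. Extinction pulses remove a chosen number of
uncovered taxa from a chosen slice onward and mark them in the ground
truth.

What the generator does **not** emulate: amplification bias and primer
mismatch, tag jumping, down-core DNA degradation gradients, spatial
structure among cores, correlated detection between communities, or the
empirical association between rarity and extinction risk (pulse taxa are
drawn at random from the uncovered pool, not preferentially from rare
taxa — so trait contrasts on synthetic records exercise the machinery
but should not be read as reproducing any particular effect direction).
Passing tests therefore show that the inference chain recovers planted
structure under realistic sparsity and noise, not that it is robust to
every taphonomic process in real sediments.

## Problem sizes and numerical choices

The test suite and analysis scripts run the generator at 4–6 cores ×
28–42 samples, 80–150 taxa and 100–200 resampling iterations, sizes at
which every planted-structure property already holds stably; the
acceptance script uses 1000 iterations for the coverage null and a
359-taxon record for its schedule. Determinism: every stochastic step
takes a seed (numpy Generator); Louvain restarts derive their seeds from
the given one. Holm correction treats all unordered ASV pairs as the
family. Constant-count ASVs have undefined correlations and stay
isolated. Degenerate inputs are defined explicitly: empty networks give
empty partitions, empty filter results give empty tables, slices without
events give net 0 / confidence 0.5, an all-zero abundance table raises,
and a zero-variance SCBD table returns the uniform vector. Rounding of
expected counts is half-away-from-zero to match printed integer counts.

## Known limitations

* The reconstruction of the balancing script (min-across-slices,
  without replacement) is one reasonable reading of a procedure whose
  details are unpublished; other balancing choices would change the
  iteration bands, though not the estimator's logic.
* The reappearance null assumes delay distributions at the reference
  slices are representative of later slices (stationarity of the
  detection process); trends in detectability masquerade as loss
  signal.
* The horizon cap makes early-slice estimates conservative rather than
  unbiased.
* Community validation absorbs extinct taxa that share a name at the
  matching rank and a community with surviving relatives, and discards
  taxa too rare to correlate — both biases point toward undercounting
  losses.
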