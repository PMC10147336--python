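# Methods

`islandrad` analyses how an island radiation assembled: which speciation
events happened within an island and which followed dispersal between
islands, and what those two routes did to morphological and ecological
divergence and to present-day co-occurrence. This note describes the
models and conventions the package implements, the choices made where a
convention had to be fixed, and what the synthetic-data generator does
and does not emulate.

## Range-evolution model

A lineage's geographic range is a subset of discrete regions, capped at
`max_range_size` regions; the state space enumerates all subsets up to
the cap plus the empty (null) range, which is kept as an absorbing
"globally extirpated" state for likelihood bookkeeping and never allowed
as a tip observation. With 11 regions and a cap of five this is 1024
states.

**Anagenesis** (along branches) is a continuous-time Markov chain:
range `A` gains an available region `k` at rate `d·|A|` (one dispersal
opportunity per occupied source region; no distance weighting — all
pairwise multipliers are 1) and loses each occupied region at rate `e`.
Units of `d` and `e` are events per million years.

**Cladogenesis** (at nodes) draws a daughter-range pair from a
family-specific table. For a single-region parent all families copy the
range into both daughters. For a widespread parent: DEC allows subset
sympatry (one daughter keeps `A`, the other one region of `A`) and
vicariance with a singleton daughter; DIVALIKE allows only singleton
vicariance; BAYAREALIKE allows only widespread sympatry (both daughters
keep `A`). The `+J` variants add founder-event speciation: one daughter
keeps `A` while the other jumps into one available region outside `A`.
Weighting must be fixed explicitly because only the parameter `j` is
conventionally reported: every non-founder event class carries per-event
weight `(3 − j)/3`, every founder event carries weight `j`, and weights
are normalised per parent range. `j = 0` recovers the base family
exactly (verified to < 1e−6 log units at `j = 1e−8`); `j` is bounded in
[0, 3]. Asymmetric daughter pairs are emitted in both orientations with
half weight, so the likelihood is invariant to child order.

**Time stratification.** Each region may carry an emergence age; the
distinct emergence ages inside the tree depth cut root-to-present time
into strata (the study system has four, bounded at 5, 1.7 and 1.1 myr
for Madeira, La Palma and El Hierro). Within a stratum the generator
blocks gains into not-yet-emerged regions; at every rootward crossing of
a stratum boundary the conditional likelihood mass of states containing
a not-yet-emerged region is zeroed. States are rate-blocked and
mass-zeroed rather than pruned from the state space, which keeps one
indexing across strata.

**Likelihood.** Felsenstein pruning over the range states: per-branch
propagation by dense matrix exponentials (`scipy.linalg.expm`,
scaling-and-squaring), branches split at stratum boundaries,
cladogenetic mixing at internal nodes, per-node rescaling against
underflow. The root likelihood is the plain sum of the root conditionals
over states — no root-state frequencies are estimated — and this choice
is recorded in every fit result so alternatives can be compared.
Correctness is pinned to two independent oracles on small instances:
exact joint summation over all internal-node state assignments (1e−6
relative agreement) and an Euler-discretised propagator (1e−3).

**Fitting and model choice.** Bounded L-BFGS-B on (log d, log e, j),
d, e ∈ [1e−9, 5] /myr, j ∈ [0, 3], from a fixed multi-start grid —
seedless and deterministic. AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1) with
k = 2 (base) or 3 (+J); the AICc sample size n defaults to the number of
tips but is an explicit argument, because different reasonable n choices
change AICc by fractions of a unit. Akaike weights are
exp(−Δ/2)-normalised over the compared set.

## Biogeographical stochastic mapping

Histories are drawn from the exact joint posterior given tip ranges:
backward pruning stores conditionals; the root state, one cladogenetic
event per node (reweighted by the daughters' subtree conditionals), and
segment-boundary states are then sampled forward; within each branch
segment the path is drawn by endpoint-conditioned uniformization — the
number of uniformized jumps from its conditional Poisson mixture, jump
times as uniform order statistics, intermediate states by the discrete
bridge over powers of `R = I + Q/μ`. This is exact with bounded work per
branch, which is why it was preferred over rejection sampling with a
resample cap; virtual jumps are discarded. Sampling is validated against
the closed-form expected gain count on a single branch and against
enumerated marginal node posteriors on a three-tip model.

Bookkeeping conventions:

* every map of an `n`-tip bifurcating tree contains exactly `n − 1`
  cladogenetic events, independent of parameters;
* **intra-island** means sympatric cladogenesis whose daughters share
  exactly one region; founder, vicariant, subset — and widespread
  sympatry on a multi-region range — count as inter-island;
* per-node calls are the majority across maps with their support
  fraction; an exact 50/50 split is reported as ambiguous and excluded
  from group comparisons;
* source/sink matrices count founder events and anagenetic gains alike
  as one source→target dispersal; a gain out of a multi-region range has
  no unique source, so the count is split 1/|A| over the occupied
  regions, preserving all marginal totals;
* widespread sympatric events are likewise split over the shared regions
  in per-island speciation counts;
* the event summary's percentages are taken over the three conventional
  classes (cladogenetic dispersal, cladogenetic sympatry, anagenetic
  dispersal); extirpations are tallied in their own row.

Map sets are reproducible from a mandatory seed; per-map TSV export and
a JSON run manifest record model, parameters and seed.

## Trait divergence

Characters are coded onto [0, 1] so one fully differing character
contributes one unit of squared distance: binary → {0, 1}; ordinal
(growth form, thermotype, ombrotype) → equally spaced levels;
quantitative ranges (elevation) → midpoint, min–max scaled by the scale
bounds; categorical multistate → one value per state, equally spaced
(maximum pairwise distance 1 — a scalar embedding cannot make *all*
state pairs maximally distant, a known limitation for characters with
more than two states). Coding is configurable per character.

A lineage's profile is the unweighted arithmetic mean over its member
taxa (missing entries skipped pairwise), so fraction-valued profiles
yield sub-unit distances even for discrete characters. Divergence at a
node is the raw Euclidean distance (RED) between the two daughter
profiles over pairwise-complete characters.

Nodes enter the comparison when recovered in every phylogenetic analysis
and highly supported (bootstrap = 100 or posterior ≥ 0.99) in at least
one — both thresholds are parameters of the selection criteria. A
subclade with inconsistent internal topology is pooled: per-analysis
REDs of its nodes are averaged into one record replacing the subclade,
which equals the flat average of the value list (unweighted). Intra- vs
inter-island groups are compared per trait class with a two-sided
two-sample t-test, pooled variance by default (Welch optional), with a
seeded permutation test available as an independent check.

## Co-occurrence and hybridization

Co-occurrence is binary per taxon pair per island — any overlap counts,
with no area weighting — and intraspecific taxa count as separate taxa.
Island rates divide the co-occurring (or hybridizing) pair count by
C(n, 2) over the island's residents; islands with fewer than two
residents are reported as undefined rather than zero. Clade-pair
percentages use C(n, 2) within a clade and n₁·n₂ between clades. Hybrid
pairs must be a subset of co-occurring pairs on the same island(s)
(validation, with an explicit override flag). Island rates join a
first-colonization-age column and report a descriptive Spearman rank
correlation.

## The synthetic-data generator

The forward simulator is a continuous-time process on lineages: founder
speciation at `f_sim` /myr (daughter seeded into an available unoccupied
region), within-island speciation at `s_sim` /myr (daughters inherit the
range), anagenetic gain/loss as Poisson processes respecting emergence
ages, extinction when a range empties. Defaults encode the study
conditions: 11 regions with the 5/1.7/1.1 myr emergence schedule, a cap
of 50 tips reached within an 8 myr window (so trees span roughly 5–8
myr), anagenetic rates at the fitted magnitudes (d = 0.021,
e = 0.044 /myr), and equal founder and within-island speciation rates
(0.35 /myr each), matching the near-equal split of the two cladogenetic
modes in the study system. Once the tip cap is reached only anagenesis
continues to the present; this keeps node ages anchored to the same
clock as the emergence schedule at the cost of a speciation-free
terminal window. Simulations that go extinct or miss the accepted tip
band are redrawn up to a retry cap, deterministically under the given
seed. The full event log replays exactly to the emitted tip ranges, and
per-node true event classes on the pruned tree are exposed for recovery
checks.

Simulator speciation is deliberately a *rate* process while the
inference model weights cladogenetic events per node — fitting the model
to forward-simulated data is therefore a controlled misspecification
stress. Where an experiment needs data from the inference model's own
law (parameter recovery at stated d, e, j), `simulate_ranges_on_tree`
draws ranges on a fixed tree under the model itself; each branch walk is
conditioned on not being absorbed into the null range, the survivorship
conditioning implicit in any observable dataset.

Trait simulation runs a jump process between levels for discrete
characters (0.04 changes /myr by default, giving each character a
handful of changes across a ~100 lineage-myr tree — the sparse variation
typical of identification characters) and reflected Brownian motion on
[0, 1] for quantitative ones (σ = 0.08 per √myr). At within-island nodes
the daughters receive opposite divergence kicks totalling δ spread over
the kicked characters, so the immediate extra RED is about δ. Kicks
propagate into all descendant taxa; ancestral inter-island comparisons
above a kicked subclade therefore also inflate — a real feature of
nested data which caps the power of a 0.05-level significance call at
~20 nodes (~0.6 at δ = 1) even though the *sign* of the intra−inter
difference is recovered essentially always. Co-occurrence simulation
draws each shared-island pair with a configurable (optionally per-island)
probability and nests hybrids within co-occurring pairs.

What the generator does not emulate: sequence data and phylogenetic
uncertainty (trees are taken as given and correct), distance-dependent
dispersal, within-island palaeo-geography, trait correlations between
characters, and area-weighted co-occurrence. Passing recovery tests on
these data therefore show the inference machinery is self-consistent and
robust to the rate-vs-weight speciation mismatch; they do not certify
behaviour under tree error or model violations not simulated.

## Numerical choices and problem sizes

Dense expm on state spaces up to ~1024 states; per-node rescaling of
conditionals; cladogenetic tables normalised to 1 ± 1e−12; stochastic
matrices checked to 1e−10. Test and acceptance experiments run on a
scaled scene — five regions (three always present, two with the 1.7/1.1
myr emergence ages) with `max_range_size` 2–3 (16–26 states), 50-tip
trees, 10 replicates, two optimizer starts — sizes chosen so the full
experiment battery completes in minutes on one core while keeping every
qualitative feature (stratification, founder events, emergence blocking)
active.

## Known limitations

* The extirpation rate `e` is weakly identified at the study's
  magnitudes: on 50-tip datasets most simulated histories contain no
  *observable* range contraction (losses from single-region ranges kill
  the lineage and are conditioned away), so the MLE of `e` sits at the
  boundary for most replicates. The estimator is consistent — median ê
  recovers truth within a factor of ~1.3 when ranges are widespread and
  losses visible — but single-dataset ê values near zero should not be
  over-interpreted. This degeneracy is a property of the model family,
  and is shared by published applications whose base-model ê estimates
  scatter widely.
* Root ranges are summed with equal weight; no outgroup-informed or
  estimated root frequencies.
* Cladogenetic weighting treats all non-founder event classes equally;
  the sympatry/vicariance weights are not free parameters.
* Categorical characters with >2 states cannot be scalar-coded with all
  pairwise distances equal to 1.
* Branch-level survivorship conditioning in the on-tree range simulator
  is not corrected for in the likelihood (standard practice, but it
  biases ê downward slightly).
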