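# Methods

## Time and tree conventions

Time runs backward: the present is age 0 and ages increase into the past,
in millions of years (My). A node's age is the tree height minus its depth,
so the farthest tip defines the present. Ultrametricity is declared when
all tip ages are within 1e-9 My of zero; complete simulated trees retain
extinct lineages and are legitimately non-ultrametric, so the property is
flagged, never enforced.

A clade's *crown age* is the root age of its tree; its *stem age* (the
split from its sister lineage) is stored separately, since Newick files
rarely carry it. The simulator records a true stem age; for user trees
without one, operations that need a stem age fall back to the crown age
with a warning. A branch length on the root of a parsed Newick string is
folded into the stem age. A lone `label:length;` input is normalised to a
proper root-to-tip branch so the length is part of the tree.

Newick parsing, serialisation and taxon pruning delegate to dendropy;
pruning suppresses degree-2 nodes with branch lengths summed, which
preserves every retained node's age exactly. That preservation is the
mechanism of origin-age inflation: removing a tip can only merge its
sister's parent node rootward.

**Interval grid.** Ages are binned into half-open intervals
`[b_k, b_{k+1})` from the present (default width 5 My). An age exactly on
a boundary belongs to the interval whose young edge it sits on. The same
tie rule governs time slices: a node exactly at slice age T counts as
already split (its child branches are the counted lineages), so the
lineage count at T = 0 equals the tip count and the count just below the
crown age is 2.

## Birth–death simulation

`simulate_birth_death` is an exact Gillespie walk over extant lineage
count, started from a crown pair (two lineages at the crown age), with
per-lineage speciation rate λ and extinction rate μ. Two stopping rules:

- `t_max`: run for a fixed duration; the crown age equals `t_max`. If the
  whole clade dies the function returns `None` — an explicit extinct
  outcome rather than an exception, since subcritical runs are a
  legitimate result.
- `n_target`: stop when the extant count first reaches n. First-passage
  stopping alone would leave the two newest tips with zero-length pendant
  branches, so the present is placed an Exponential(n(λ+μ)) dwell after
  the n-th speciation — the time the process actually spends at count n.
  First-passage stopping is known to distort tree-age distributions
  relative to sampling a uniformly chosen moment at count n; the
  fixed-duration mode is therefore the default for bias ensembles, and
  the fixed-size mode is used where conditioning on n is the point (e.g.
  Kendall–Moran recovery, where growing to fixed size makes the total
  branch length Gamma(n−1, λ) and (n−2)/S exactly unbiased).

The stem age is recorded as crown age + Exponential(λ), the waiting time
to the first speciation on a stem lineage. All draws flow from a single
seeded NumPy generator per operation; seeds are explicit everywhere.

## Sampling schemes

- `uniform`: keep exactly `max(1, round(f·n))` tips without replacement.
  A fixed count (not per-tip Bernoulli) keeps test ensembles' sizes
  deterministic.
- `one_per_clade`: keep one uniformly chosen tip from each maximal clade
  whose crown age is younger than a cutoff, emulating one-species-per-genus
  backbone trees in which sampling is biased toward clade representatives.

Sampling delegates to pruning and hence never changes a retained node's age.

## Trait evolution

Brownian motion with rate σ² (trait² per My): each child state is its
parent state plus Normal(0, σ²·branch length). With
`cladogenetic_jump_sd > 0`, an independent Normal(0, jump²) is added at
the origin of every daughter branch of a branching event, so each daughter
jumps independently at speciation; σ² small with large jumps approximates
purely cladogenetic change, σ² alone is purely anagenic. States exist for
every node of the complete tree (extinct lineages included). When positive
traits are needed (photosynthetic-capacity-like variables analysed on log
scale), states are treated as log-traits and exponentiated.

The four-taxon worked-example fixture carries placeholder tip traits
{1, 2, 3, 4} and synthetic internal states (child means) purely for
structural completeness.

## Naive estimators under study

Implemented literally, so their failure modes can be measured:

- naive origin age: parent-node age per tip, on whatever tree is supplied;
- interval medians: per-interval median trait over contributing tips, even
  counts averaged over the two middle values, empty intervals absent (NaN)
  and excluded downstream, never imputed as zero;
- ln(n)/t with natural log and stem-age t (log base recorded in output
  metadata);
- Kendall–Moran (n−2)/S — the crown-conditioned pure-birth ML rate; the
  recovery ensemble above is its correctness oracle;
- rate through time: "prune everything younger than T" is operationalised
  as counting the lineages crossing age T, the only reading that yields a
  well-defined n per interval; the per-boundary elapsed time is
  stem age − T.

## Bias measures

Origin-age truth τ_i is the tip's parent age in the fully sampled
reconstructed tree. Inflation is summarised both as the mean of per-tip
ratios, `100·mean(o/τ − 1)` (default), and as the ratio of means, since
"average inflation" is ambiguous between the two; both are reported.
The log–log r² is the squared Pearson correlation of (ln o, ln τ).

The true ancestral trait per interval is the mean over all complete-tree
lineages alive at the interval midpoint of the linearly interpolated state
between branch endpoints (the Brownian-bridge mean given the simulated
endpoints); midpoints are used because interpolation is unbiased there.
A node exactly at the midpoint contributes once per child branch,
mirroring the slice convention. Naive-vs-true absolute errors are defined
only where both sides exist. The sampling-sensitivity probe re-runs the
median series with one uniformly chosen tip removed and reports which
interval medians changed.

Under sparse sampling the corruption shows up across the whole median
series (misassigned, inflated origins), so the headline ASR-bias statistic
is the mean absolute error over defined intervals; conditioning on "the
oldest nonempty interval" compares different intervals between sampling
fractions and is dominated by which rare trees have any old contributors
at all, so it is not used as a summary.

## Association test

BAMM-style posterior rate regimes are out of scope; the DR statistic
(inverse equal-splits) supplies tip rates — a deliberate substitution,
since tip rates have fewer identifiability problems than deep-time rate
reconstructions. Correlation is Pearson on log rate vs log trait (or
Spearman). Significance comes from permutations: the naive tip shuffle is
provided but is anticonservative when rates and traits share phylogenetic
signal — the reason structured permutations exist — so calibration claims
are made only under exchangeable nulls (i.i.d. traits); the structured
alternative shuffles regime-level rates across regimes. p-values use the
add-one rule, two-tailed via |r| (one-tailed exposed), with ties counted
as extreme (conservative). `type1_power_sim` simulates trees, draws
log-traits as β·log(DR) + Normal(0, sd²), and tabulates rejections; β = 0
is the null.

## Ensemble sizes and defaults

Bias ensembles use pure-birth trees with λ = 0.1 /My — a plausible order
for vascular-plant radiations and large enough that 40–50 My of growth
yields trees of a few hundred tips: 100 trees (t = 40, tips ≥ 20) for the
inflation-vs-f sweep over f ∈ {0.05, 0.2, 0.5, 1.0}; 200 trees (t = 50,
f = 0.05) for the rate-through-time comparison at boundaries 0 and 25 My;
500 fixed-size (n = 50) trees for Kendall–Moran recovery; 2,000
replicates (t = 20) for the extant-count calibration against 2e^{λt};
400 replicates at B = 999 permutations for null calibration, checked
against the binomial envelope at α = 0.05 and by a Kolmogorov–Smirnov
uniformity test at α = 0.01. These sizes put Monte-Carlo error well below
the effects being demonstrated while keeping a full run in seconds.

## What the generator does and does not emulate

It produces constant-rate birth–death trees, uniform or
one-representative-per-clade sampling, and (log-)Brownian traits with
optional speciational jumps. It does not model time-varying or
state-dependent rates, protracted speciation, fossil sampling, or
phylogenetic uncertainty; real megaphylogenies also mix calibration error
and nonrandom sampling in ways no scheme here captures. Passing tests
therefore demonstrate the *direction and mechanism* of the naive
estimators' biases under controlled conditions, not the magnitude to
expect in any particular empirical dataset — magnitudes depend strongly
on the true sampling fraction and tree shape.

## Numerical choices and degenerate inputs

Ultrametricity and age-tie tolerance 1e-9 My throughout. Correlations on
constant vectors are errors (undefined), except the log–log r² of an
exactly identical naive/true age vector, which is reported as 1.
Single-tip trees have no parent split and are rejected by origin-age
operations; Kendall–Moran requires n ≥ 3; permutation tests require B ≥ 99
and ≥ 3 shared tips. Sampling-percentage arithmetic is exact rational
before two-significant-figure formatting. Pipeline stage seeds are derived
from one master seed via named SeedSequence streams, so every output is
reproducible from the config alone.
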