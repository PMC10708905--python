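# Methods

## Data model and aggregation

Input data are daily-resolved interaction records (day, row actor,
column actor, optional count ≥ 1). A *block* is a set of records from
consecutive, nonoverlapping windows: fixed-length runs of calendar days
starting at the first observation day, calendar months, the full
period, or explicit date ranges. Within a block, multiple interactions
between a pair count once; the binary incidence matrix only includes
actors with at least one interaction in the block, so every node has
degree ≥ 1 and the normalization radicand 2L − R − C + 1 is positive.

Presence is inferred, not observed: an actor's presence set is exactly
the set of days it appears in a record. The sampling period f counts
*observation days* (days with at least one record anywhere in the
block), not calendar days — days nobody was recorded are treated as
unsampled rather than as universal absences. Copresence n_ij is the
size of the intersection of the two presence sets, so a linked pair
always has n_ij ≥ 1.

## The four link models

All models treat links as independent Bernoulli draws and conserve the
expected link count L exactly:

* **ER**: p_ij = L/(RC).
* **Degree distribution**: p_ij = k_i/(2C) + k_j/(2R). The total is
  conserved exactly; each node's expected degree is k_i/2 + L/(2R)
  (and the column analogue), i.e. individual degrees are conserved in
  the aggregate while each node is pulled halfway toward its category's
  mean degree. This is a property of the formula itself, not an
  implementation choice.
* **Phenology**: p_ij = 1 − q^{n_ij}, one global q per network. q is
  the unique root in [0, 1] of Σ_k x_k q^k = Z (x_k the copresence
  histogram, Z = RC − L the zeros of the incidence matrix). The
  polynomial is nondecreasing with g(0) = x_0 and g(1) = RC, so a root
  exists iff x_0 ≤ Z, equivalently L ≤ #{pairs with n_ij ≥ 1}; the
  solver checks this first and raises a model-infeasibility error
  naming both counts otherwise. Boundary roots q = 0 (every copresent
  pair linked) and q = 1 (L = 0) are returned exactly; interior roots
  come from bracketed Brent iteration with xtol = 1e−14 (residual well
  below 1e−10). Pairs with n_ij = 0 get probability exactly 0.
* **Presence**: identical machinery with n_ij replaced by
  ⌈(|P_i| + |P_j|)/2⌉, the rounded-up mean number of presence days of
  the pair; rounding up keeps every entry ≥ 1 so the polynomial is
  always solvable. q is re-solved against this variant histogram.

## Nestedness

The spectral radius of the bipartite adjacency matrix is computed as
the largest singular value of the incidence matrix (the adjacency
spectrum is ±σ_k plus zeros). Normalization divides by
√(2L − R − C + 1), the maximum possible spectral radius for a graph
with L edges and R + C vertices of degree ≥ 1; the single link K_{1,1}
normalizes to exactly 1.

ER baselines draw each of n_graphs (default 10,000) matrices with
independent links at probability L/(RC) — an expected-L ensemble, not a
fixed-L configuration model. Each draw is normalized after removing its
all-zero rows and columns, using its own realized link count; removal
does not change the singular values but keeps the radicand positive for
every nonempty draw. Graphs with isolated nodes are kept (not
redrawn); draws with no links at all contribute ρ = 0 and are counted
separately. Model realizations are scored the same way: each
realization keeps the full R×C frame for confusion statistics but is
normalized on its nonempty submatrix with its own link count, the same
convention applied to the empirical network.

Δρ̃ = (ρ − ρ_ER)/(ρ_emp − ρ_ER) rescales a model value between the ER
baseline (0) and the empirical level (1); values above 1 (model more
nested than the data) are legitimate and occur. Within a pipeline run
all models of a window share one ER baseline draw, so their Δρ̃ values
are directly comparable.

## Assessment and backbone

Confusion counts classify each cell of a realization against the
empirical matrix; TP + FN = L in every realization. The phi
coefficient, F-score, Youden's J and TPR are computed per realization;
a statistic whose denominator vanishes (zero marginal) is recorded as
an explicit not-a-result (NaN, with a count), never as 0. Because the
models conserve L in expectation, FP ≈ FN, making F1 ≈ TPR and
phi ≈ J; under the ER model F1 approximates the fill.

The backbone test splits the empirical links of each realization into
true positives and false negatives, keeps both subsets on the full R×C
frame, and drops all-zero rows/columns only for normalization (the
matrices being much sparser than full networks, this is where the
convention matters; the reduced dimensions are used). Subset ER
baselines match the full frame dimensions and the subset's own link
count, and are cached per link count with a seed derived from (seed, R,
C, L) so identical subsets always meet identical baselines. Excess
nestedness is (ρ − ρ_ER)/(1 − ρ_ER) for each subset; the test reports
the per-realization ratios ρ_TP/ρ_FN and excess_TP/excess_FN and the
fraction of realizations in which each exceeds 1. No distributional
test is assumed: "significant" means that fraction reaches a
configurable level, 0.95 by default. Realizations with an empty TP or
FN subset are skipped and counted.

A caution for small matrices: a handful of scattered links with no
shared rows or columns attains the normalization bound (ρ = 1), and
genuinely random scatter tends to sit *below* the ER mean (negative
excess). Both backbone ratios can therefore only exceed 1 when the FN
subset is mildly structured; on tiny examples the test is illustrated
with a staircase TP subset against a dense remainder rather than
against pure scatter.

## Synthetic generator

`PhenologySpec` defaults describe the reference study condition used
throughout the tests: 50×50 actors over 120 days, activity windows with
uniform onset and geometric duration of mean 40 days (about a third of
the period, giving strongly heterogeneous overlap), presence probability
0.8 per in-window day, and interaction probability p_true = 0.3 per
copresent day. Durations are truncated at the period end; actors that
would never be active are redrawn. All randomness flows from the single
spec seed.

Generated data satisfy the phenology model *exactly* (given the true
calendars), which the tests exploit twice. Parameter recovery: fitting
against the generator's known calendars recovers p_true without bias
(measured means 0.100/0.304/0.691 for p_true 0.1/0.3/0.7). Fitting
against calendars re-inferred from the records is biased upward at low
interaction rates — an actor present but idle on a day is invisible, so
copresence is undercounted (at p_true = 0.1 the fitted p roughly
doubles). This is a property of the observational procedure itself,
worth keeping in mind when interpreting fits to sparse real data;
recovery experiments therefore use the true calendars.
Self-consistency: with no preference injection, the fitted model's
ensemble-mean Δρ̃ against its own generated network is ≈ 1, and this
holds at *every* aggregation level, because the restriction of the
generative process to any sub-window is again the phenology model.
Consequently this generator does not produce the empirical pattern of
Δρ̃ rising from ~0.25 (weekly) toward ~1 (annual): that pattern
requires nested structure in the data that within-window copresence
cannot explain. What the generator does reproduce is (i) the fattening
right tail of the copresence distribution as windows lengthen while the
median barely moves, and (ii), when preference links are injected, the
largest model–data discrepancy at the shortest windows (there as
Δρ̃ > 1, since one-day preference links depress empirical nestedness
most in small blocks), shrinking toward 1 with aggregation.

Preference injection adds round(preference_fraction × L_base) extra
links to unlinked pairs drawn from the lowest quartile of positive
copresence, one record each on a randomly chosen shared day; pairs
without a shared day can never be injected, and any shortfall is
reported, not raised. Injected links are the ones the phenology model
should misclassify, enabling F < 1 regimes.

What passing tests do *not* show about real data: the generator has
contiguous activity windows, a single global p, no abundance or
sampling-effort variation, no persistent pair affinities, and no
within-day structure. Conclusions about those features need real data.

## Problem sizes and tolerances

Ensemble defaults follow the method's convention: 1,000 model
realizations for assessment and 10,000 ER graphs for baselines. The
test suite scales the Monte-Carlo work to what its assertions need:
2,000-graph baselines and 200 realizations per dataset for the
self-consistency check (3 replicate datasets), 4,000-graph baselines
for the deterministic backbone example, 20 replicate seeds per p_true
for recovery. Conservation is asserted to 1e−8, the polynomial
residual to 1e−10, the SVD-vs-power-iteration agreement to 1e−9, and
Monte-Carlo means to 4 standard errors of the relevant ensemble.

## Known limitations

* One global p per network; no pair-specific preferences or loyalty.
* Binary networks only; counts are read but discarded at binarization.
* Presence inference from records undercounts copresence in sparse
  data (see above); the package offers no correction, only the
  generator-side true-calendar path for controlled experiments.
* The backbone "significance" criterion is an ensemble fraction, not a
  calibrated hypothesis test.
* Sub-daily timing, spatial structure and abundance effects are out of
  scope.
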