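# Methods

## Model

The package evaluates a multi-target screening campaign as a pair of
compounds × targets matrices: experimental K<sub>i</sub> values (nM) and
docking/rescoring scores (lower is better unless declared otherwise). Both
are discretized to three ordered categories and compared with the L1 metric
on the resulting integer ranks. The discretization is the modeling step;
everything after it is exact combinatorics.

Three cell states are distinguished on the experimental side. A positive
K<sub>i</sub> is a measurement; **ND** ("no detectable binding") is also a
measurement — it is categorized red and participates in every statistic;
**MISSING** (never tested) is neither, and is excluded from distances,
denominators and CBD_max. Conflating ND with MISSING would reward a method
for being wrong about untested compounds, so the two sentinels are kept
apart end to end (ND is stored as `+inf`, MISSING as `NaN`).

## Partition schemes and boundary conventions

In vitro: green for K<sub>i</sub> strictly below `green_below`
(default 1000 nM); yellow up to `yellow_upper` inclusive (default
unbounded — any measurable affinity); red otherwise, and always for ND. The
sensitive variant uses 100/1000 nM. "Below" is read strictly, so
K<sub>i</sub> = 1000 nM is yellow; at exactly 100 nM the sensitive scheme
also says yellow. The yellow buffer exists precisely to absorb assay
uncertainty at the green/red border.

In silico, two modes:

* `range_fraction` (default 0.20/0.20): with span = |worst − best| of the
  observed scores, a score within `green_frac`·span of the best is green,
  within (`green_frac`+`yellow_frac`)·span yellow, else red. Boundaries are
  inclusive toward the better color (a score exactly at the 20% mark is
  "within the first 20%"). A zero-width span (constant column) is all
  green. The range is taken per column by default — each receptor's docking
  run has its own score scale — with a `global` scope available; nothing in
  the method forces either choice, so it is a flag.
* `fixed_cutoff` (defaults −100/−90, suitable for rescoring energies):
  green at or below `green_max`, yellow at or below `yellow_max`, red
  above; the boundary points again go to the better color. Fixed cutoffs
  are meaningful only for lower-is-better scores and the scheme refuses
  other orientations.

Percent-inhibition readouts have no numeric rule here; a pre-categorized
G/Y/R column can be supplied through the category-matrix CSV format
instead.

## Distances and derived statistics

For rank matrices v (in vitro) and s (in silico) with ranks in {0..R}
(R = 2 ternary, R = 1 binary), the per-entry distance is |v − s| where both
sides are ranked; totals decompose exactly into per-compound and per-target
sums. Statistics:

* `avg_bpc` = total / (number of compounds with ≥ 1 compared entry).
  The denominator is compounds, not entries — the unit is "blocks per
  compound".
* `cbd_max(v)` = Σ max(v, R − v) over ranked entries of the in vitro
  matrix: the distance of the adversarially worst in silico assignment. For
  binary matrices it equals the number of ranked entries. It is defined
  against v alone (the fixed ground truth), which is what makes
  `cbd_rel = total / cbd_max` comparable across runs that share the in
  vitro data.
* Binarization (2→1, 1→1, 0→0) is a per-entry contraction, so binary CBD
  never exceeds ternary CBD on the same data.

Reported summaries round half-up to 2 decimal places (`round2`); raw floats
are kept in machine-readable output. Division by a zero `cbd_max` or a
zero-variance correlation is reported as not-applicable (NaN / null), never
as 0.

## Randomization baselines

"Better than random" is quantified against two nulls: `uniform` (each in
silico rank drawn independently and uniformly from {0..R} — random 0-1-2 or
0-1 distributions) and `permutation` (the observed in silico ranks shuffled
within each target column, preserving the column's rank multiset and hence
the method's category frequencies). Uniform is the default. The closed form
E|v − U| per entry (ternary: 1 for v ∈ {0,2}, 2/3 for v = 1; binary: 1/2)
checks the sampler. The summary quantile is the fraction of null totals
≤ observed, ties counted — lower CBD is better, so small quantiles mean
strong performance. One seeded generator per run; the seed is logged in
every output.

## Enrichment

ROC/AUC of actives vs decoys uses the Mann–Whitney convention for ties
(single diagonal segment, half credit per tied pair), making the
trapezoidal area identical to the pair-counting statistic
(wins + ties/2)/(n_act·n_dec). AUC is invariant under strictly monotone
score transforms; swapping the labels complements it. No early-enrichment
metrics are computed.

## Run comparison

Families of labeled runs are compared by the Pearson correlation of a
per-run statistic; `avg_bpc` is the default field since it is the quantity
quoted per run for every family, with `total` and `cbd_rel` selectable.
r and r² are reported raw and rounded.

## Synthetic benchmark generator

`generate_dataset` emulates a screening campaign: per cell,
log₁₀K<sub>i</sub> ~ Uniform(lo, hi) (default 0–5, i.e. 1 nM–100 µM —
log-uniform rather than log-normal so all three categories are populated
evenly); an ND fraction; scores = intercept + slope·log₁₀K<sub>i</sub> +
N(0, σ) with defaults slope 2, intercept −12 placing scores in a
docking-like (−12, −2) band, and σ = 1 as the default score noise. ND cells
still get scores — real docking scores non-binders — drawn uniformly from a
band just beyond the worst measurable score (width 10% of the measurable
span, floor 1 score unit). Placing ND strictly beyond the measurable scores
is what makes a noiseless simulation perfectly recoverable: with cutoffs at
the score-images of the Ki cutpoints the CBD is exactly 0, the anchor the
test suite uses.

What the generator does *not* emulate: correlated errors across targets
(a scoring function's systematic bias), heavy-tailed score noise,
compound-series structure, and selectivity patterns between related
subtypes. Tests passing on this generator show the bookkeeping and the
statistics are right, not that any docking protocol is accurate.

`generate_actives_decoys` draws actives ~ N(−separation, σ) and decoys
~ N(0, σ), lower-is-better, giving an analytic AUC of Φ(separation/(σ√2))
to check the ROC machinery.

## Problem sizes and numerical choices

Tests and the acceptance script use the campaign-scale layouts throughout:
39 × 3 (test set) and 88 × 3 (validation set) matrices, 10,000 null draws,
up to 200+200 enrichment scores, 20 seeds × 3 noise levels for the
noise-monotonicity trend, and exhaustive enumeration up to 6-entry matrices
for the CBD_max oracle. All randomness flows through
`numpy.random.default_rng` with explicit seeds.

## Design choices where the method is open

* Aggregating several receptor structures of one target: `per_structure`
  (default; every structure is its own comparison), `best_score`,
  `mean_score` or `single`, chosen per run — no single choice is canonical
  when four homology models face one binding assay column.
* The range-fraction scope (per-column vs global) and the DSX-style
  recoloring scope are flags for the same reason.
* CLI exit codes follow click's convention (0 success, 2 usage error,
  1 data error).
* HTML traffic-light rendering is optional; CSV is canonical.

## Limitations

Three fixed categories (no learned or multi-class cutoffs); no weighting of
targets or compounds; CBD treats all rank disagreements of equal size as
equally bad regardless of direction (over- vs under-prediction); the
permutation null conditions on the observed category frequencies and is
therefore stricter than the uniform null; correlations between run families
are descriptive — no significance testing is attached.
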