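# Methods

This note documents the models, conventions and design choices behind
`vdtscreen`, in the package's own terms. It states no empirical result that
the test suite or the analysis scripts do not themselves compute.

## Deficit scoring

Each neuropsychological test contributes a demographically adjusted T-score
(mean 50, SD 10 in a seronegative reference population). The deficit grade is
a monotone step function: 0 for T ≥ 40, then one point per 5-point band
(35–39 → 1, 30–34 → 2, 25–29 → 3, 20–24 → 4) with a floor of 5 below T = 20.
The bin edges are exposed as module constants because the upstream literature
fixes them by citation rather than restating them. Domain deficits are plain
arithmetic means of their member tests; the Global Deficit Score (GDS) is the
mean of the seven domain deficits. Both classification cutoffs are
*inclusive*: GDS ≥ 0.5 flags HAND, domain deficit ≥ 1 flags within-domain
impairment. One published prevalence table is headed "domain deficit
score > 0" while the accompanying text applies the ≥ 1 rule; this package
follows the text and leaves the threshold configurable
(`domain_cutoff`). Missing test scores are an error by default (the source
cohort excluded the one invalid assessment rather than imputing); an optional
policy averages a domain over its available tests. The three-level HAND
category (none / asymptomatic-or-mild / dementia, the last at GDS ≥ 1.5 by
convention) is computed but deliberately not used by the selection pipeline.

## Telemetry features

Derived channels use forward (not centered) first differences so the units
stay interpretable: acceleration = Δspeed × rate (mph/s), jerk =
Δacceleration × rate (mph/s²). Derived samples align with the trailing raw
sample of each difference, so zone membership applies unchanged. Heading
misalignment is the wrapped absolute difference of heading and road heading
(degrees, in [0, 180]). Below-limit indicators are 1 where the vehicle is at
least 10 (resp. 15) mph under the posted limit; their summaries are
percent-of-time variables. Zone membership is per-sample via the zone track;
summary statistics use all samples of the scope, and the global statistics
are statistics of the *concatenated* drive, not averages of zonal
statistics. Standard deviations use the n−1 denominator. Medians and IQRs
(Q3 − Q1) use linear-interpolation quantiles. Columns constant across
participants are removed and logged; with a fixed route, large numbers of
structurally constant zonal columns are expected (a zone with no pedestrians
yields zero pedestrian collisions for everyone).

The composite VDT Error Score is a non-negative weighted sum of the eight
higher-order error counts. The production weights are proprietary and
unpublished; the shipped defaults (collisions heaviest: 5/5/3/10, then 2/2/1
for signal, sign and navigation errors and 4 for teleports) are an explicit,
overridable stand-in. Rank-based screening is unaffected by the particular
positive weights only through the ordering they induce, which is why the
vector is part of the config rather than a hidden constant.

## Split-consensus selection

Stratified folds come from scikit-learn's `StratifiedKFold` (shuffled,
seeded); the training set of split s is the complement of fold s. The
original analysis pinned its splitting seed to 0 inside its own software
stack, which is not bit-reproducible from the outside; the contract here is
determinism given the seed, not replication of the original folds. The
Kruskal–Wallis H uses mid-ranks with the standard tie correction (count
variables guarantee ties); a within-training-set constant variable gets
H = 0 rather than an error. p-values are the χ² (df = groups − 1) upper
tail. Ranking is by descending H with ties broken in favour of the variable
appearing first in the original column order (a stable sort). The consensus
is the set intersection of the S top-k prefixes, ranked by the median H
across all S splits; an empty intersection is a valid result, and
consensus(k₁) ⊆ consensus(k₂) for k₁ ≤ k₂ by construction.

k defaults to 100 and is a configuration constant. The elbow scan of the
mean-top-k-H curve is advisory only. Because the `kneed` package is not
available in the runtime environment, the knee detector is implemented
in-package as the chord-distance formulation of the kneedle idea: normalize
the curve to the unit square and take the point of maximum perpendicular
offset from the chord joining the endpoints, returning "no knee" for a
numerically straight line. For smooth diminishing-returns curves this is the
maximum-curvature point kneedle estimates.

### Null-behavior caveat

Any two training sets share S − 2 of the S folds (with S = 5, 75% of their
samples), so the per-split H rankings are strongly positively correlated.
The often-quoted null argument — a variable has probability (k/M)^S of
entering all S top-k lists "by chance" — assumes independent lists and is
therefore an idealization only. Measured on this package's own generator
with no planted effects and label-independent features (M ≥ 1000, k = 100,
S = 5), the null consensus has median size ≈ 15, not 0: the intersection
filter controls selection noise far less strongly than the independence
arithmetic suggests. The corresponding acceptance test asserts the
idealized behavior and fails by design; the stability report prints the
analytic probability alongside this caveat. Consumers should treat the
consensus as a variance-reduction device, not a false-positive guarantee.

## Stability metrics

Jaccard similarity compares the top-k lists as sets. The Kendall quantity is
the Fagin partial-list distance: every unordered pair from the union of the
two lists contributes 1 if the lists determinably disagree, 0 if they
determinably agree (an element absent from a list is implicitly ranked below
its top k), and the penalty p (default 0.5, the neutral convention) when
both elements sit in one list only. The literature this follows sometimes
calls the quantity a "correlation", but it is a distance: 0 for identical
lists. The normalizer is the distance of two disjoint lists of the same
length at the same p, making the range exactly [0, 1] for every p. A
consequence worth noting: the *raw* distance is non-decreasing in p, but the
normalized value need not be, because the normalizer also grows with p
(two reversed identical-set lists score 1/(k² + p·k(k−1)), decreasing in p).
The property suite asserts monotonicity on the raw distance
(`topk_kendall(..., normalize=False)`).

## Secondary statistics

Prevalence contrasts use the two-sided Fisher exact test (the conventional
"exact test" for 2×2 HAND contrasts). The 2×2 chi-square is Pearson's
without continuity correction — the only variant consistent with published
statistics of order 10⁻⁵ on near-independent tables, which Yates' correction
would floor to 0. The rank-sum comparison reports the Mann–Whitney U of the
first sample (the convention R's `wilcox.test` prints as W) with the
tie-corrected normal approximation. Spearman associations are computed per
(consensus variable, domain-impairment flag) cell; the Bonferroni family is
every tested cell, m = |consensus| × 7 — the most conservative reading —
and both significance tiers (per-cell α and α/m) are emitted so either
convention can be read off. Cells with a constant variable or flag are
reported as undefined (NaN), never significant. All tests are two-sided.

## Synthetic cohort generator

The generator states a world; it is not tuned to outcomes.

* **Labels first.** HAND labels are assigned to round(n × prevalence)
  participants (default 62 × 0.57 → 35). CNPA T-scores are then drawn
  conditional on the label: unimpaired profiles keep every test at T ≥ 40
  (deficit 0); impaired profiles get 2–5 randomly chosen domains with all
  tests in the 25–35 band (domain deficit ≥ 2, hence GDS ≥ 4/7 ≥ 0.5). GDS
  scoring therefore recovers the labels exactly, giving an exact oracle; a
  configurable misclassification rate (default 0) swaps the conditional
  distribution to emulate imperfect labeling.
* **Telemetry.** The route is fixed: alternating out-of-zone and zonal
  blocks, identical for every participant, with a posted-limit menu
  (25/35/45 mph) and per-zone road headings. Channels are stationary draws
  per (channel, zone) cell: a per-participant location offset ~ N(0, τ²)
  plus within-session noise ~ N(0, σ²) (optionally AR(1) with the marginal
  SD held fixed; no published autocorrelation value exists, so the default
  is white). τ, the between-participant SD, is the "scale unit" in which
  effect sizes are expressed (speed 4 mph, lane offset 0.15 m, centre offset
  0.5 m, heading 1°, steering 0.01, extra channels 1.0). Vehicle dynamics
  are *not* simulated — the analysis only consumes summary statistics, and
  stationary draws keep planted effects exactly interpretable.
* **Planted effects.** An informative (channel, zone) cell shifts the
  HAND group's location offset by ±(effect size × τ). A location shift
  translates the cell's min/max/mean/median summaries identically and leaves
  its SD untouched, so informative variables come in blocks of four;
  the generator plants ⌈n_informative/4⌉ cells and records the realized ids
  and signed shifts in the ground-truth sidecar. Derived channels sharing
  the shifted source (e.g. speed-vs-limit for a shifted speed cell) inherit
  the effect; recovery is scored against the recorded ids only.
* **Errors.** Event counts per type are negative-binomial (dispersion 2)
  with group-specific means (defaults roughly double the rates in the HAND
  group), giving the composite error score a higher HAND-group median and a
  long right tail, as the published score distribution shows. Event times
  are uniform over the session; each event carries the zone under the
  vehicle at that time.
* **Scale.** Defaults are the desk-scale reduced route (10 channels, 5
  zones, 600 s at 10 Hz → ~450 retained variables); the full-scale shape
  (~40 channels, 22 zones, thousands of variables) is reachable by config.
  Property-test worlds that need ≥ 500 or ≥ 1000 variables raise the channel
  count and shorten sessions to 120 s; these sizes were fixed before any
  test outcome was observed.

What a green test does *not* establish: the generator draws i.i.d. samples
within zones (no realistic vehicle dynamics, no gaze behavior, no
channel-to-channel kinematic coupling beyond the derived-channel algebra),
uses a stylized CNPA score distribution, and plants clean location shifts.
Passing parameter-recovery tests therefore demonstrates the pipeline's
correctness and sensitivity under the stated world, not clinical validity.

## Degenerate inputs and numerical conventions

Sessions shorter than 3 samples are rejected (jerk undefined). A participant
absent from a zone is an error by default (the fixed route guarantees
exposure) with an opt-in NaN policy. Stratified splitting requires at least
S members per class. Constant variables yield H = 0, rank last under the
tie-break, and produce undefined association cells. Elbow detection needs
≥ 3 points and returns "none" on straight lines (relative tolerance 1e-6).
Quantiles interpolate linearly. The Abs% median difference is
|median_HAND − median_noHAND| / |median_HAND| × 100, printed as an integer
percentage and as the literal `UNDEF` when the HAND-group median is 0 — the
only convention that reproduces all twenty published rows, including both
UNDEF rows.

## Known limitations

* The consensus procedure's false-positive behavior is materially worse than
  the independence idealization (see the null-behavior caveat); any use for
  inference should calibrate against permuted labels.
* The error-score weights are stand-ins; absolute score levels are not
  comparable to the commercial instrument.
* Real replay channels (gaze channels in particular) are consumed as generic
  extra channels; no gaze-specific derivations are provided.
* The published variable counts (2,921 computed / 2,601 retained) are
  route-dependent and cannot be reconstructed from public information; the
  package asserts only computed ≥ retained.
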