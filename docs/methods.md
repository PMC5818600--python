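# Methods

This note documents the statistical model behind `metabomoa`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that make the pipeline deterministic.

## Study structure and data model

The unit of organization is the *work package*: one experimental batch with
its own vehicle controls (DMSO only, default n = 16), treated groups
(default n = 8 per dose, high dose HD and low dose LD), pooled reference
replicates (default n = 16) and blanks (default n = 16). Doses come from a
range finder: HD is the largest tested concentration keeping total protein
at ≥ 80% of control, LD = HD/3. Measurements live in an `AbundanceMatrix`
(samples × metabolites, missing values explicit NaN, never silent zeros)
over a fixed `MetabolitePanel` — 117 known + 77 unknown intracellular
analytes, 70 + 19 in the supernatant. Only the known/unknown totals of
those panels are externally fixed; the per-class allocation (lipids
dominant, then amino acids, energy metabolites, …) is a package choice used
consistently by the simulator and the packaged scenarios.

## Normalization

Three stages, in this order:

1. `pool_normalize` — divide each value by the median of the pool reference
   samples for that metabolite. Removes inter-/intra-instrumental drift;
   pool samples themselves are normalized so that their residual spread is
   the technical-variability estimate.
2. `median_normalize` — divide each sample row by its median over the
   declared subset (default: the full panel), `X_med = X / median(X_i·)`.
   Removes per-sample multiplicative factors (cell-number differences)
   *exactly*: `normalize(c · row) = normalize(row)` for any c > 0, and the
   post-condition `median over subset = 1` holds to representation error.
3. `log_transform` — elementwise log10; downstream statistics operate on
   this scale.

Medians of even-length vectors are the midpoint of the two central order
statistics. Missing values are excluded from every median and propagate
(no imputation). Blanks are normalized like any sample but excluded from
all statistics by default; no blank subtraction is performed.

## Metabolic profiles

For one treatment/dose against the vehicle controls of the same work
package(s), each metabolite gets a two-sided Welch t statistic with
Welch–Satterthwaite degrees of freedom, computed explicitly (the t
distribution tail comes from scipy). Default α = 0.05, no multiple-testing
correction — the profile is a fingerprint, not a discovery list; an FDR
option exists at the API level via the stored p values. The reported effect
size is the ratio of group medians on the linear ratio scale, and the
direction of a significant metabolite is taken from that ratio (more robust
than the t sign on near-degenerate metabolites). Metabolites with undefined
t (zero variance in both groups with equal means, or n < 2 after missing
values) are flagged `degenerate`, kept in the table, and excluded from
similarity computations — they never become NaN inputs downstream. Two
separated point masses (zero variance, different means) get t = ±inf,
p = 0.

Controls are matched within work package because every package runs its own
vehicle controls; cross-package pooling is available behind a flag but off
by default, so batch offsets cancel inside each comparison.

## Similarity and PWC

Treatment similarity is the Pearson correlation of two profiles' t-value
vectors over shared non-degenerate metabolites (≥ 3 required). The
pair-wise comparison (PWC) ranks all database profiles against a query by r
descending, ties broken by (treatment, dose) ascending, so rankings are
independent of insertion order.

## Patterns

* **General toxicity**: metabolites significant in the same direction in at
  least `min_fraction` (default 0.75) of the high-dose profiles. The
  threshold is configurable because "most of the treatments" is inherently
  a judgment call.
* **MoA derivation**: candidates are metabolites significant with identical
  direction in *all* (≥ 3) reference high-dose profiles, minus the general
  pattern members. The general pattern passed in is the established,
  database-wide resource (for packaged scenarios, the scenario's shared
  signature; it can equally be a freshly derived one): deriving it from the
  handful of compounds inside one comparison would let MoA members leak
  into it whenever the same-MoA compounds approach the concordance
  threshold.
* **Refinement**: greedy hill-climb on Youden's J = sensitivity +
  specificity − 1. Sensitivity is scored on labelled same-MoA high-dose
  profiles *excluding the references* (they defined the candidate;
  scoring them would be circular), specificity on labelled different-MoA
  profiles, including compounds with no specific MoA. Moves are single
  member removals or additions of metabolites significant-concordant in
  ≥ 2 references; the single move with the largest strict J gain is taken,
  ties prefer the smaller pattern and then the lexicographically smallest
  metabolite id. J never decreases; the search is deterministic and stops
  at the first local optimum (pattern spaces are exponential; exhaustive
  search is not attempted).
* **Matching**: with per-metabolite null probability p0 = α/2 (significant
  *and* in the expected direction), the match p value is the exact
  one-sided binomial tail P(Bin(m, p0) ≥ k); a profile matches when
  match_p < 0.05. k = 0 gives match_p = 1 exactly; k is nonincreasing in
  unmatched padding, so inflating a pattern can only weaken its matches.
  The binomial construction is this package's documented choice of match
  statistic; labelled alternatives (e.g. permutation of metabolite labels)
  can be layered on the same MatchResult interface.

## QC and PCA

RSD = 1 − 10^(−sd_log) with the sample (n−1) standard deviation of log10
values per (work package, role). Controls give total variability, pools
technical; the biological component is
1 − 10^(−sqrt(max(sd_total² − sd_tech², 0))) with negatives clamped to zero
and counted — with 16 replicates per cell, occasional negative differences
are expected sampling noise, not errors. Per-package summaries aggregate by
median across metabolites (configurable to mean).

PCA standardizes each metabolite (center, unit variance, ddof = 1) and
takes a full SVD — no randomized solver — with the sign convention that the
largest-magnitude loading of every component is positive, making scores
reproducible across runs, metabolite orderings and BLAS builds (up to
ties). Zero-variance metabolites are dropped and reported.

## Factorial linear models

`fit_factorial` is a reporting aid: per-metabolite OLS (statsmodels) on the
categorical factors substance, dose and work package with all interactions,
type-II F tests. It runs on treated samples only: including vehicle
controls as a pseudo-substance level makes substance × dose structurally
aliased (controls have no dose), whereas on treated samples the full
factorial is estimable. Factors with a single level are dropped from the
formula; rank-deficient designs are repaired by removing aliased terms,
highest interaction order first, and the removed terms are reported. The
dose factor is coded with LD as the reference level so dose coefficients
read as HD-above-LD shifts.

## The synthetic-data generator

Values follow a multiplicative log-normal model on log10 scale:

    log10 X = log10 baseline_j + batch(wp) + bio + tech + planted effect

* baselines log-uniform over 3 decades (instrument dynamic range);
* `batch(wp)`: one scalar per work package shared by all its samples and
  metabolites (sd 0.05 log10) — exactly the kind of shift that median
  normalization absorbs;
* biological noise (sd 0.040) for controls and treated samples, technical
  noise (sd 0.032) for everything including pools; blanks are
  baseline × 0.01 with technical noise, excluded from statistics.

The two noise defaults are set so the back-transformed RSDs land in the
bands a well-run targeted platform reports: pool (technical) RSD
≈ 7% (5–10% band), control (total) RSD ≈ 11% (10–15% band). Planted
signatures are dose-monotone (default 2.0-fold at HD, 1.4-fold at LD,
directions alternating within a signature) and recorded in a
`PlantedTruth` for recovery tests.

Packaged scenarios:

* `null_study` — one sham treatment, nothing planted (type-I calibration).
* `general_toxicity` — six hepatotoxicants in three work packages, all
  carrying a shared 38-member signature (9 identified lipids, 16 unknowns,
  6 energy metabolites, 5 amino acids, 1 amino-acid-related,
  1 carbohydrate).
* `enzyme_inducers` / `peroxisome_proliferators` — seven treatments in four
  work packages: three reference compounds and two further compounds of the
  focus MoA, one compound of the opposite MoA, one untargeted compound; the
  shared general signature on all seven, a 9-member inducer signature
  (5 lipid/complex lipid, 3 amino acids, 1 related) and a 12-member
  proliferator signature (6 lipids, 3 amino acids, 1 related, 2 other) on
  their compound sets.

What the generator does **not** emulate: chromatography/MS physics,
retention drift, compound-specific chemistry, missingness mechanisms
(values are complete unless the user introduces gaps), heavy-tailed or
correlated metabolite noise, and treatment effects outside the planted
signatures. Passing recovery tests therefore demonstrates that the
derivation machinery is correct and calibrated under the assumed noise
model — not that real HepG2 data would yield these particular patterns.

## Expected behaviour under the defaults

Under the packaged conditions the pipeline's statistical behaviour is
predictable from first principles, and the test suite checks exactly this:
the null scenario yields ~5% significant metabolites; the general scenario
recovers its 38 members essentially always (per-profile power at 2-fold
effects and these noise levels is ≈ 1); MoA derivation returns the planted
9/12-member sets in ≥ 90% of seeds. The dominant failure mode is a
different-MoA or untargeted profile reaching k = 2 chance hits on the
pattern (probability P(Bin(m, 0.025) ≥ 2) ≈ 0.02 for m = 9, 0.035 for
m = 12 per negative compound), which makes it match spuriously and leads
refinement to trade one member for specificity; with two labelled negatives
per scenario this occurs in roughly 4–7% of seeds and shifts the count by
one. This is inherent to refining against a finite labelled database at
α = 0.05, not an implementation artifact.

## Problem sizes

Packaged scenarios produce 64–304 samples × 194 metabolites per study;
recovery statistics use 50 seeds per scenario and calibration 100 null
studies (~19,400 metabolite-tests), sizes at which every reported quantity
is stable yet the whole suite runs in well under a minute of compute.

## Known limitations

* Greedy refinement finds a local optimum of J; with very small labelled
  databases J is a coarse (step-function) objective.
* The match test treats pattern members as independent under the null;
  correlated metabolites (e.g. co-regulated lipids) make the nominal
  match p anti-conservative.
* The factorial fit assumes homoscedastic Gaussian residuals per
  metabolite; the profiling path (Welch) is the primary statistic.
* `pwc_rank` is O(n²) in database size — fine for hundreds of profiles,
  not for millions.
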