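# Methods

## Interval model

All coordinates are 0-based half-open (`[start, end)`, BED convention), so
abutting intervals share no bases and the minimal interval is 1 bp. Strand
is ignored everywhere: none of the quantities computed here (overlap
fractions, length bins, relative anchor positions) are orientation-aware.
Tracks are kept sorted by (chrom, start, end) with duplicates and mutual
overlaps permitted, because a domain genuinely can overlap several
instances of the same feature.

**Sum rule.** `total_overlap_bp` sums the per-instance overlaps rather
than taking the union, so `fraction_of_overlap` can exceed 1 when
instances stack inside a domain. This is deliberate: the feature encodes
"how much of this feature's signal falls on the domain, per bp of domain",
and merging instances would erase multiplicity. A union-merge variant is
available (`build_feature_matrix(..., merge=True)`, CLI
`--merge-instances`) for sensitivity checks; for disjoint-instance tracks
the two agree exactly.

**Nearest TSS.** TSS intervals are reduced to midpoints. The distance from
a domain to a point is 0 if the point lies inside, otherwise the distance
to the nearer boundary coordinate; ties break toward the smaller TSS
coordinate so the assignment is deterministic. Domain edges (rather than
midpoints or summits) were chosen because a broad domain's body, not its
center, is what a promoter assignment should respect; this is a package
decision, not a property of the data.

## Feature matrix

Rows follow the domain track's coordinate order, columns the input track
order; no hidden sorting or filtering. Domains with all-zero features are
retained — dropping them would bias the length distribution the regression
is trying to explain. The target is raw length in bp (no transform by
default): predicted-vs-observed comparisons are then in the natural units,
at the cost of sensitivity to the long right tail (see Limitations). TSV
round-trips preserve 10 significant digits.

## Length regression

`RandomForestRegressor` (scikit-learn) with 100 trees, bootstrap sampling,
⌊√m⌋ candidate features per split (floored, minimum 1), and
variance-reduction (squared-error) splits — the standard regression
impurity; classification impurities like Gini do not apply to a continuous
target. The forest itself is standard machinery and is delegated to
scikit-learn; everything around it (OOB bookkeeping, evaluation,
significance calling) is this package's code.

**Out-of-bag evaluation.** Reported accuracy is the Pearson correlation
between observed lengths and OOB predictions: each training domain is
predicted by averaging only the trees whose bootstrap sample excluded it
(~37% of trees in expectation). OOB is the default because it is an honest
internal held-out estimate; resubstitution (`basis="resubstitution"`, CLI
`--resubstitution`) is reported alongside for comparison and is always at
least as high. Domains that appear in every bootstrap sample (possible
only for very small ensembles) have undefined OOB predictions and are
flagged and excluded from the correlation. OOB membership is recovered
per tree from scikit-learn's bootstrap index helpers, so the flags are
exact rather than inferred.

Predictions are convex combinations of training targets (tree leaves
average target values), so they never leave the training range — the
forest cannot extrapolate beyond the longest training domain.

## Significance by contrast attributes

For each of the m features a contrast attribute — a seeded random
row-permutation of that column, preserving its marginal distribution
exactly — is appended, and the forest is refit on all 2m columns.
Importance is mean decrease of impurity averaged over trees, normalized so
all 2m scores sum to 1 (normalization before thresholding is recorded in
the report; unnormalized scores are available via `normalize=False`).

The SD of the m contrast scores estimates the noise floor; the cutoff is
2×SD. All 2m scores are sorted in decreasing order, consecutive
differences are scanned, and the threshold is the larger score of the
*last* pair whose difference exceeds the cutoff. Features scoring at or
above the threshold are significant. Scanning the full augmented list
(rather than original features only) matters in the corner case m=1, where
the original list alone has no consecutive pair; contrast columns are
never themselves reported significant. When no gap exceeds the cutoff the
threshold is +∞ and nothing is significant — the conservative reading of
an undefined case. `repeats > 1` averages scores over independent
permutations before thresholding, trading runtime for stability; the
default is the literal single-shot procedure.

## Anchor localization

Domains are ranked by length (ties by start coordinate) and split into k
contiguous equal-frequency bins (k=5 default), sizes differing by at most
one with remainders at the shorter ranks. Equal-frequency rather than
equal-width bins because domain lengths are heavily right-skewed:
equal-width quintiles would leave the upper bins nearly empty.

Both anchors of every pair are tested for domain overlap independently and
an anchor overlapping several domains contributes to each. The anchor is
clipped to the domain, mapped to relative coordinates (pos − start)/L, and
accumulated on a G-cell grid (G=100 default) with fractional occupancy at
cell edges: cell g receives overlap-bp/(L/G), so one anchor spanning the
whole domain contributes 1.0 to every cell, and the profile mass
Σ coverage × (L/G) equals the clipped overlap bp exactly. Bin profiles are
means over all of the bin's domains including anchor-free ones (per-domain
mean normalization; a pooled mode would weight domains by length).

The feature-length correlation uses, per domain, the summed full length of
all overlapping track instances (consistent with the sum rule) and
Spearman correlation, since only monotonicity is claimed.

## Synthetic data

The generator emulates the regime of broad-domain analysis on one
synthetic chromosome:

- **Domain lengths** ~ 10^Normal(3.2, 0.4) bp, i.e. log-normal with median
  ~1.6 kb, central 95% roughly 260 bp–10 kb and a tail into tens of kb —
  a right-skewed spread from hundreds of bp to tens of kb. Domains are
  placed left-to-right with uniform random gaps of 100–5000 bp; a
  CapacityError is raised if the configured span cannot hold them.
- **Informative tracks**: each domain carries one contiguous instance
  covering fraction `f = clamp01(sigmoid(slope·z) + ε)` of it at a random
  offset, with z the standardized log10 length and ε ~ N(0, noise_sd).
  The sigmoid keeps fractions in [0,1] with a monotone planted effect; any
  monotone link would serve. Defaults: 6 informative tracks, slopes
  alternating +2/−2, noise sd 0.05.
- **Decoy tracks** (default 14) draw the pre-noise term from an
  independent standard normal, giving the same marginal shape with no
  length relation.
- **Anchors**: one per domain, 500 bp wide, plus a partner outside the
  domain. *Uniform* mode draws the center uniformly over the domain span
  extended by half the anchor width at each end: after clipping, expected
  per-base coverage is exactly flat, whereas a center confined to [0, L]
  would depress the outermost grid cells by up to 2× (boundary effect).
  *Edge* mode places the center within the outer 10% of the domain at
  either end (fair coin), with the band tightening linearly with length
  rank so longer domains are more edge-concentrated.

Per-stage seeded RNG streams (seed × CRC32(stage name)) make every output
bit-identical under a fixed `SimulationConfig`.

What the generator does **not** emulate: read-level noise, peak-calling
artifacts, multiple chromosomes, inter-feature correlation structure
(decoys are mutually independent; real TF tracks are heavily correlated),
GC/mappability biases, or anchors unrelated to any domain. Passing the
recovery tests therefore shows the pipeline's statistics behave correctly
under a known truth, not that real predictor sets will reach any
particular accuracy.

## Benchmark sizes and observed behavior

The standard benchmark is 2000 domains × (6+14) tracks; a forest fit takes
~1 s and the full significance procedure ~2 s on one core, so multi-seed
checks stay cheap. On this benchmark the OOB observed-vs-predicted Pearson
r is ≈0.87 (seed 7; 0.78–0.92 over ten seeds). This is essentially the
information-theoretic ceiling of the planted configuration, not a model
deficiency: the sigmoid link saturates for |z| ≳ 1.5, so the overlap
fractions carry almost no resolution among the longest domains — exactly
the domains that dominate a Pearson correlation on raw bp lengths. A
Bayes-optimal posterior-mean predictor under the true generative model
reaches r ≈ 0.87 on the raw scale (≈0.98 on the log scale), and the forest
matches it. Steeper-than-saturating links, lower noise, or a log-scale
target would all raise the raw-scale ceiling; the defaults are kept as the
package's documented study conditions.

## Pipeline

One global seed derives per-stage seeds by hashing the stage name
(`stage_seed`, values < 2³¹), so a stage rerun in isolation reproduces its
in-pipeline behavior. Every stage writes a re-loadable artifact (BED/
BEDPE/TSV/JSON); the run is restartable from the feature-matrix TSV.
Failures write a `FAILED` marker naming the stage and keep partial
outputs. Logging goes to stderr and `run.log`.

## Known limitations

- Raw-length Pearson correlation is dominated by the longest domains;
  log-scale evaluation is more stable but is not the default reported
  number.
- The single-shot significance procedure has permutation-to-permutation
  variability; under a null target it flags one spurious feature in a
  small fraction of runs (use `repeats` to stabilize).
- Overlap features are presence-based; signal intensity is ignored.
- No multiple-chromosome placement in the simulator; cross-chromosome
  logic is exercised only through the interval operations' own tests.
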