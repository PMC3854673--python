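# Methods

## The selection model

A feature (gene or probe) is scored between two phenotype classes by a pair
of statistics computed on log2-scale expression:

* **mean difference** `Δ = mean(class 1) − mean(class 0)` — the log2 fold
  change. It is deliberately *not* standardized: dividing by a variance
  estimate would re-introduce exactly the normality sensitivity the second
  statistic is there to control, and would duplicate its role.
* **Mann-Whitney U p-value** (two-sided) — a rank test of stochastic
  ordering, invariant under monotone transforms of the data. For group sizes
  where the smaller group has ≤ 8 samples and the pooled values carry no
  ties, the exact permutation null of U is used; otherwise the normal
  approximation with continuity correction and midrank tie correction.

The two-way filter retains features with `|Δ| ≥ t1` **and** `p ≤ t2`. Each
retained feature carries a direction (`up_in_class1` iff Δ > 0; an exact zero
goes to class 1 by convention, and is excluded by any positive `t1` anyway),
so output lists split into "high expression → class 1" and "high expression
→ class 0".

### Threshold grid

Thresholds are searched over a data-driven lattice:

* `t1` axis: 20 quantiles of the observed `|Δ|` distribution, from the 50th
  to the 99th percentile. Quantile-based axes make the grid scale-free across
  platforms; values below the median of `|Δ|` would only admit noise, values
  above the 99th percentile leave nothing to select.
* `t2` axis: 10 values log-spaced from 0.1 down to
  `max(min observed p, 1e-6)`. A p cutoff looser than 0.1 stops being a
  signal-to-noise control; the lower end adapts to the smallest p the data
  can produce (for small cohorts that is the exact-test resolution
  `2/C(n, n1)`).

The default 20 × 10 grid gives 200 threshold combinations. Each cell is
scored by repeated stratified k-fold cross-validation (default 5 repeats ×
5 folds) of the full filter + DLDA pipeline, with both filter statistics and
the classifier recomputed on each training fold alone. Held-out scores are
pooled within a repeat into one AUROC (per-fold AUROC on ~12-sample folds is
too unstable); the cell's performance is the mean and SD over repeats. The
winning cell has the highest mean AUROC; ties break toward fewer selected
features (parsimony), then toward the stricter (smaller) p cutoff, then the
larger `t1`, then cell order — fully deterministic.

Computationally, per training fold the per-feature statistics and the
per-feature DLDA discriminant contributions are computed once; each grid cell
is then a masked sum, so the 200-cell search costs barely more than a single
cell.

### Final selection and the performance floor

After the grid search, the winning pair is applied to statistics computed on
*all* provided samples to produce the reported feature list (the CV surface
remains the performance estimate). If even the winning cell's CV mean AUROC
is below a floor (default 0.65), the selector returns an empty set: a dataset
without a cross-validatable signal should yield no markers, not its noise
maxima. The floor value is a judgment call — 0.65 sits roughly 1.5 null SDs
above chance for cohorts of 60–150 samples — and is configurable.

### Iterative discovery

To enumerate *all* informative features rather than only the strongest set,
selection is repeated with previously selected features removed from the
matrix. Iteration stops when a round's CV performance drops below the floor,
a round selects nothing, or `max_rounds` (default 10) is reached. Rounds are
disjoint by construction. The stop rule (floor / empty / max-rounds) is this
package's concrete design; all three knobs are exposed.

## The classifier

DLDA: Gaussian classes with shared diagonal covariance. Per feature, class
means and the pooled within-class variance
`s² = ((n0−1)v0 + (n1−1)v1)/(n0+n1−2)`, floored at
`1e-8 + 1e-3 · median(s²)` so constant features cannot blow up the
discriminant. Priors default to training frequencies (configurable to
uniform); near-balanced stratified folds make this nearly flat. The
discriminant is evaluated in the centered form
`d(x) = Σ 2(μ1−μ0)(x − (μ0+μ1)/2)/s² + 2 log(π1/π0)`, algebraically equal to
the difference of squared Mahalanobis-type distances but exactly zero (in
floating point too) at the between-centroid midpoint with equal priors. Ties
at d = 0 go to the larger prior, then class 0. The simplicity is deliberate:
with tens of samples and thousands of features, anything richer cannot be
cross-validated at acceptable cost, and the gains live in feature selection,
not classifier tuning.

## Performance estimation

* `auroc` is the rank-based estimator with midrank ties, identical to
  `U/(n0·n1)` — consistent with the filter's own U statistic.
* `cv_evaluate_thresholds` cross-validates one threshold pair. Folds through
  which no feature passes score their held-out samples 0 exactly, so overly
  strict cells are comparable (a grid cell nothing ever passes scores 0.5).
* `nested_cv` runs the entire grid search on each outer-training partition
  with an inner CV, then fits the winner on that partition and scores the
  outer held-out fold. By default the grid *axes* are also rebuilt from each
  outer-training partition, since the `t1` quantile axis depends on labels
  and would otherwise leak marginally. One AUROC per outer repeat from pooled
  held-out scores; the SD is across outer repeats.
* `cv_evaluate_fixed_features` cross-validates the classifier on a
  pre-specified feature set. It is the correct tool for a signature fixed
  *before* seeing the data — and doubles as the demonstration of selection
  bias when the set was chosen on the same samples (on pure noise it reports
  AUROC ≈ 0.9 where the honest nested estimate is ≈ 0.5).

On pure-noise cohorts of 60 samples × 1,000 features, the honest nested-CV
AUROC is centered at 0.5 with an SD across datasets of ≈ 0.10–0.11. That
spread is a property of cross-validating flexible pipelines on 60 samples —
an independent scikit-learn pipeline (diagonal Gaussian classifier, pooled
held-out scores) shows the same SD — and is noticeably wider than the
binomial AUROC SD at n = 60 (≈ 0.074), because held-out scores share training
folds and the estimate is conditional on the one realized dataset. Single
null datasets can therefore land outside ±0.12 around chance without any
leakage being present; leakage shows up as a *systematic* shift (≈ +0.4 for
the pre-filtered CV above), not as scatter.

## Signature scoring

A signature is two disjoint directional gene lists. The score is the plain
sum of log2 expression over `up_poor` minus the sum over `up_good`; class
"poor" is called when the score exceeds zero (a score exactly at the
threshold goes to "good" — a measure-zero event needing a deterministic
rule). No scaling, centering or cohort-specific tuning is applied anywhere,
which is the point of the construction for cross-platform validation.
Missing signature genes raise an error rather than being dropped: silent
dropping changes the score's scale and the meaning of the zero cutoff. With
equal list cardinalities the score is invariant to per-sample location
shifts, giving robustness to sample-wise normalization offsets.

## Preprocessing

Expression matrices carry a scale flag (`intensity` vs `log`) so the log2
transform cannot be applied twice. Flooring low intensities (default 40)
before log2 is an explicit caller decision — appropriate for some platforms,
not others — never implicit. Probe-to-gene collapsing keeps the probe with
the largest interquartile range (75th − 25th percentile, linear
interpolation) across samples; IQR ties break by file order, unmapped probes
are dropped with a logged count. Missing values are rejected outright.

## Survival endpoints and strata

Two dichotomization rules produce the binary labels the classifier needs:
**extreme groups** (event strictly before `early` = 5 years vs event-free
strictly beyond `late` = 10 years, intermediates dropped) for discovery, and
**fixed horizon** (event by `t` vs followed past `t`; censored before `t`
dropped, an event after `t` counts as event-free at `t`) for validation
endpoints. The boundary conventions — strict inequalities for the extreme
rule, event time ≤ horizon as positive — are stated here because they decide
individual samples. Clinical stratification intersects exact covariate
criteria; samples missing a cited covariate are excluded from the stratum
rather than raising.

## The synthetic cohort generator

The generator emulates an oligonucleotide-array cohort: per-gene log2 values
at baseline mean 8, SD 1, exponentiated to intensity scale so the flooring /
log path is on every test's critical path; a binary class at configurable
balance; exponential survival times whose log-hazard rises 1.0 per SD of the
true (planted) risk score, with uniform-in-[0, T] censoring of a configurable
fraction; ER / nodal covariates from a joint stratum distribution (defaults
≈ 77% ER+, 49% node+, independent); ages uniform in [30, 52].

`effect_size` is always the class-mean shift of an informative gene in
within-class-SD units, whatever the shape, so moments are directly checkable.
The non-normal shapes concentrate the same mean shift in a per-gene random
subset of class-1 samples: `bimodal` shifts half the class by 2× the effect,
`outlier_spike` a quarter by 4×. These construct the regime the two-way
filter exists for — subset effects inflate the within-class variance faster
than the mean, crippling t-type statistics while the mean difference (and,
more weakly, the rank test) still see the signal. The subsets are drawn
independently per gene: the per-gene marginal (all any filter statistic sees)
is the same mixture either way, but independent subsets keep the multi-gene
signal combinable by a classifier, which a single shared subset would cap at
AUROC 0.5 + fraction/2 regardless of gene count.

What the generator does **not** emulate: probe-level effects, spatial or
batch artifacts, correlated co-expression modules, platform saturation, or
informative censoring. Passing tests on these cohorts therefore demonstrate
the statistical machinery (honesty of CV, recovery under known effect sizes,
the non-normal advantage), not robustness to real-platform noise.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 60–200 samples and 400–1,000
features with 5×5-fold CV — the scale of a single-site prognosis study, and
comfortably fast because of the masked-sum grid engine (a full 200-cell grid
search on 120 × 1,000 takes ≈ 0.5 s; nested CV with a 5×5 inner loop ≈ 3 s
per cohort). The exact Mann-Whitney path is reserved for min group size ≤ 8;
p-values are clipped into (0, 1]; all fold layouts, inner seeds and
generator draws derive deterministically from user seeds, making every
selection, surface and cohort bit-reproducible.

## Known limitations

* Two classes only; no multi-class DLDA, no shrunken centroids.
* The threshold pair is the only tuned hyperparameter; the statistic pair
  itself is fixed (mean difference + Mann-Whitney), with a Welch-t helper
  provided as a baseline/drop-in, not a tested selection path.
* The performance floor and iterative stop rule are pragmatic defaults, not
  estimates; on datasets whose true effect sizes hover near the floor the
  returned list size is sensitive to it.
* `select_features` reports statistics recomputed on all samples after
  CV-based threshold choice; the attached CV performance refers to the
  thresholds, not to the final list (which has seen all the data).
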