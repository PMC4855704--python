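# Methods

## The simulated process

The package simulates two-round Angoff standard setting as a pure
measurement model: item difficulty is not modelled, the true cut-score of
every item (and hence the test) is fixed at 0, and everything a judge
contributes is decomposed into latent attributes on standardised scales.
A judge's decision on an item is a weighted mixture of two components:

* a **random error** component `Ji ~ N(0, A_j)` whose dispersion `A_j` is
  the judge's (inverse) accuracy — the operational definition of
  expertise here;
* a **stringency** component, the mean of an item-level draw around the
  judge's stringency location `Sji ~ N(S_j, 1)` and a coupling draw
  `Sa ~ N(1 - A_j, 1)` that makes more expert judges (small `A_j`)
  systematically more stringent.

The mixing weights `Wa_j, Ws_j` are per-judge constants drawn as
`(N(0,1)+3)/3`; the cell score divides by their sum, so each judge's two
components are relative influences. All five judge-level quantities are
constant across that judge's items; only the five item-level draws are
refreshed per cell. Round 2 differs from round 1 only through peer
influence: each cell score is multiplied by the judge's leadership weight
`(mean(Lji, La) + 3)/3` — centred near 1, larger for judges with high
latent leadership `L_j` and, through `La ~ N(1 - A_j, 1)`, for experts —
and the grand mean over the `n*k` cells is taken with the same divisor as
round 1. Because the weights are random with mean ≈ 1 and are not informed
by any data, round 2 is mathematically a noise-injection on round 1; the
paired comparison quantifies how much precision that costs.

Modelling assumptions worth keeping in mind: judge attributes are
independent and normally distributed; attributes are independent of item
difficulty (which is absent); the two rounds share all draws except the
leadership weights, so the paired design isolates the influence effect;
and panels are independent across replicates and grid cells.

## Parameters

| parameter | default | units / scale | role |
|---|---|---|---|
| `judge_counts` | 5, 10, 15, 20, 30, 50, 80 | judges | grid axis |
| `item_counts` | 5, 10, 15, 20, 30, 50, 80 | items | grid axis |
| `replicates` | 100 | panels per combination | Monte-Carlo resolution |
| `accuracy_transform` | `abs` | — | maps the N(0,1) accuracy draw to a valid dispersion |
| `weight_floor` | 1e-6 | weight scale | keeps `Wa+Ws > 0` (binds with prob. ≈ 0.00135 per weight) |
| `zero_stringency` | `False` (library default); `True` in `as_published()` | — | centres the `Sa` coupling at 0 |
| `round2_normalize` | `False` | — | divide round 2 by `Σ weights` instead of `n*k` |
| `master_seed` | caller-supplied | — | sole source of randomness |

All attribute scales are standardised (SD 1, means 0 or 1), so cut-scores
are in standardised score units and effect sizes are directly comparable
across grid cells.

## The accuracy transform and the centred coupling

Two choices in the data-generating process are genuinely open and are
resolved as explicit configuration rather than silently:

1. **Nonnegative dispersion.** The accuracy draw is standard normal, but a
   dispersion cannot be negative. The default maps it through `|z|`
   (half-normal, mean `sqrt(2/pi) ≈ 0.798`); `square` (`z²`, mean 1) and
   `truncate` (`max(z, 0)`) are preserved as alternatives. The transformed
   value is also what enters the `1 - A` coupling means.

2. **Centring of the accuracy→stringency coupling.** Under any transform
   with `E[A] ≠ 1`, the coupling `Sa ~ N(1 - A, 1)` has a non-zero mean,
   which propagates into a deterministic bias of the round-1 cut-score of
   `E[Ws/(Wa+Ws)] · (1 - E[A])/2 ≈ +0.05` under the `|z|` default. A biased
   grand mean contradicts the defining property of the published results
   this package reproduces — per-combination confidence intervals that all
   cover the true cut-score, and a negligible net attribute effect — and
   inflates every precision statistic (measured on the full grid: mean
   |round-1 score| 0.080 instead of ≈ 0.058, and a paired round effect
   around −0.45 instead of ≈ −0.1). `AngoffExperiment.as_published()`
   therefore centres `Sa` at 0 (`zero_stringency=True`), which is the only
   configuration consistent with those properties; the literal uncentred
   reading stays the library default and is one flag away
   (`angoffsim reproduce --literal-table`). The resolved choice is logged
   on every run.

One consequence is honest and documented rather than hidden: the partial
correlation between within-panel SD (judge agreement) and |cut-score|
(precision) is positive but small under the half-normal accuracy default —
about 0.06–0.12 across master seeds (under 1.5 % of variance). The
magnitude of this correlation is governed by the heterogeneity and
skewness of the judge-effect distribution (a sample's SD is coupled to its
|mean| only through non-normality and variance heterogeneity), which the
standardised parameters above do not uniquely pin down: the squared
transform, for instance, raises it to ≈ 0.35. The package reports whatever
the configured process yields and makes no attempt to tune this value.

## What the generator does and does not emulate

The generator *is* the study's data source — there is no empirical input.
It emulates panels of judges whose biases and error dispersions are
mutually independent draws from normal families, rated against items of
identical (zero) difficulty. It does not emulate: item difficulty or
item-by-judge interaction, non-normal or correlated judge attributes,
judges updating on examinee performance data between rounds, or panel
dynamics richer than a multiplicative influence weight. Passing tests
therefore validate the behaviour of the Angoff *aggregation machinery*
under these idealised conditions — unbiasedness, the value of added judges,
the cost of the second round — not claims about any particular real panel.

## Numerical and design choices

* **Seeding.** Each panel's generator is
  `default_rng(SeedSequence(master_seed, spawn_key=(n_judges, n_items,
  replicate_id)))` — a collision-free scheme under which any sub-grid
  reproduces the identical panels of the full run. Attribute draws are
  column-wise per panel (all accuracies, then all stringencies, ...), so a
  panel is a fixed function of its stream.
* **Confidence intervals.** Student-t on the per-combination panel
  cut-scores (df = 99 under defaults). A single-panel combination yields an
  undefined CI and a logged warning.
* **Within-panel SD.** Sample SD (ddof = 1) across judges of judge-mean
  round-1 scores; defined as 0 for a single judge.
* **Deciles.** Panels are ranked by the panel-mean attribute with a stable
  sort (ties have probability 0) and split into 10 equal groups — exactly
  490 panels each on the default grid, near-equal otherwise. The
  stringency × accuracy interaction uses 10 × 3 bins by default,
  configurable.
* **Partial correlation.** Both variables are residualised on an intercept
  plus covariates by least squares; r is the Pearson correlation of
  residuals, p from t with df = n − 2 − #covariates. With no covariates
  this is exactly Pearson (tested against scipy and cross-checked against
  pingouin). Covariate control is linear, matching standard practice.
* **Paired effect size.** `d = mean(diff)/sd(diff)` with
  `diff = |score1| − |score2|`; d < 0 means round 2 is less precise.
  Zero-variance differences with zero mean report t = 0, p = 1.
* **Precision analyses default to round 1**; every analysis accepts a
  round switch. No multiple-testing correction is applied.
* **Degenerate inputs.** `A = 0` gives a degenerate (exactly zero) error
  draw; weight draws below the floor are clipped; empty panels, empty item
  sets, non-finite table values and duplicate panel keys are rejected at
  validation.

## Problem sizes

The default full grid (4900 panels, ≈ 1.6×10⁷ judge-item cells) simulates
in a few seconds on one CPU, so the test suite and the reproduction script
run the complete experiment rather than a scaled-down version; bulk
Monte-Carlo checks of distributional constants use 10⁵–10⁶ draws, and the
zero-bias diagnostic uses 10⁴ small panels.

## Known limitations

Attribute families are fixed (normal/half-normal); the influence model is
a single multiplicative weight rather than convergence dynamics; the
agreement–precision correlation depends on distributional choices the
standardised parameterisation leaves open (see above); and conclusions
about optimal panel design transfer to real panels only insofar as real
judges resemble the assumed attribute model.
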