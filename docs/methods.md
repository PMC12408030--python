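# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Predictive model

Each analysis cell (modality × measure × sex-group × timepoint) gets its
own linear ridge regression of one behavior score on 68 regional features.
The solver is the closed form on centered data,

    w = (Xcᵀ Xc + λ I)⁻¹ Xcᵀ yc,    b = ȳ − x̄ · w,

implemented spectrally: the standardized training Gram matrix is
eigendecomposed once per training set, after which the solution for any λ
(and any response vector) is a diagonal rescaling in the eigenbasis. This
is algebraically identical to solving the normal equations — the test suite
checks agreement with a direct solve, with scikit-learn's Ridge and with a
numerical minimizer of the penalized objective — and it is what makes
permutation inference affordable, because everything that depends only on
the features is computed once.

**Resampling.** Outer loop: repeated random train/test splits, default
100 splits at 80/20 (k-fold is available via `ModelConfig(scheme="kfold")`).
Repeated splits give a stable mean and a per-split accuracy distribution;
accuracy is aggregated as the arithmetic mean of per-split Pearson r
between observed and predicted held-out scores, not the r of pooled
predictions. Feature standardization and response centering use training
statistics only, applied unchanged to test rows; inner folds re-standardize
on their own training portion.

**Penalty selection.** Default grid: 16 log-spaced values in [10⁻³, 10⁴],
spanning under- to over-penalized regimes for standardized 68-feature
problems. The inner criterion is the mean k-fold held-out correlation
between observed and predicted values (default k = 5); exact ties break
toward the larger penalty, and if every inner correlation is undefined
(constant response) the largest grid value is used with a warning. Note a
property of correlation scoring: it is invariant to prediction scale, so
under a pure-noise response neither end of the grid is systematically
preferred — selection is near chance level rather than defaulting to heavy
shrinkage. This is tested as such.

**Degenerate cases.** A test split whose observed values are constant gets
no accuracy (recorded as missing and excluded from the mean, counted in the
results object); a cell below the minimum size (default 100 complete rows)
is excluded at assembly time with a manifest entry rather than an error,
so a 162-cell batch never aborts midway.

## Permutation inference

The null distribution for a cell's mean accuracy is built by shuffling the
behavior vector across participants and re-executing the complete pipeline
— penalty selection included, so the null is honest to everything the
observed statistic was allowed to do. The empirical p is the one-sided
add-one estimator p = (1 + #{null ≥ observed}) / (1 + B); only high
accuracy counts as signal, since negative accuracy is failure, not
evidence. Implementation detail: permutations are evaluated in batches
against the precomputed feature-side quantities of the observed pipeline;
a test asserts this is numerically identical to naive re-runs. Default
B = 1,000 for production runs and 100 in the simulation studies (a warning
is raised below 100, where p resolution is coarse).

FDR correction is Benjamini-Hochberg step-up, applied within each
behavioral scale family — the 4 BIS/BAS measures form one family and the 5
UPPS-P measures another, per modality × sex-group × timepoint batch. The
exact family composition beyond "within scale" is a declared choice of this
package.

## Importance maps and comparisons

Backward-model weights are converted to forward activations with the Haufe
transformation: a_j = cov(x_j, Xw) over training rows (denominator n − 1,
training rows only, no variance normalization of the fitted scores — scale
cancels in cosine similarity, the only downstream consumer). Activations
are computed per outer split and averaged; applying the transformation to
averaged weights instead is a near-equivalent alternative, and
per-split-then-average is the documented choice here. Each map also carries
a display variant divided by its maximum absolute value (peak exactly ±1;
an all-zero map is flagged rather than divided).

Cosine similarity is computed on the raw mean importance values. Cells that
did not reach significance are masked out of the similarity matrix
entirely, so a female/male contrast only appears when both sexes' cells are
significant; cross-timepoint contrasts are gated the same way by
construction, an extension of the cross-sex rule.

## Behavioral descriptives

Group differences use Mann-Whitney U: midrank U with the tie-corrected,
continuity-corrected normal approximation, switching to the exact
distribution when n₁ + n₂ ≤ 12 with no ties. The measured worst-case error
of the normal approximation against exhaustive enumeration at n₁ = n₂ = 6
is ≈0.0155 absolute p, which is why the exact method is used in that
regime. The baseline vs two-year comparison treats the visits as
independent samples even though participants overlap — this mirrors the
unpaired design of the analysis the package implements; a paired Wilcoxon
option is provided but non-default, and the dependence caveat stands.
"Full correlations" among the nine measures are Pearson (full as opposed to
partial, not as opposed to rank; a Spearman option exists) on
pairwise-complete cases, with constant measures yielding flagged NaN
entries.

## Synthetic cohorts

The generator emulates the structure of a large two-visit youth cohort:

- **Defaults as study conditions**: 9,099 baseline participants, 70.7%
  retained at the two-year visit, 48% female (the cohort being emulated is
  approximately balanced; the exact fraction is a one-time choice),
  68 bilateral regions per modality.
- **Features**: per modality, latent regional values are multivariate
  normal with unit variances and a covariance that combines exponential
  decay along the atlas ordering with an extra contralateral-homologue
  component (regions j and j+34), giving a structured, provably
  positive-definite default. Males receive a smooth ±0.2 SD per-region mean
  offset by default.
- **ICV**: log-normal (median ≈ 1.5 × 10⁶ mm³, σ_log = 0.09); stored SA and
  GMV are the latent value times ICV, so proportional correction recovers
  the latent exactly (tested to 10⁻¹²).
- **Behaviors**: y = Σ_m X_m·w_m(sex) + ε with Gaussian noise; weights are
  shared plus an optional sex-specific delta. Default weights give each
  modality ≈1% of behavioral variance per measure — an asymptotic accuracy
  ceiling near r ≈ 0.1, the scale of brain-behavior effects reported in
  large youth cohorts. Scores are generated continuous; an optional
  discretization hook exists for robustness checks, since real scale scores
  are Likert-derived and non-normal.
- **Timepoints**: year-2 rows are a retention subsample with freshly drawn
  features (optionally autocorrelated with baseline via
  `feature_autocorr`); the analysis treats timepoints separately, so
  independence is the default.
- **Ground truth**: the generator returns per-cell effective weights and
  exact signal fractions (for the pooled sex group, the R² of the best
  linear predictor under the two-sex mixture, handling sex-specific means
  and weights); `theoretical_max_accuracy` is the square root — the
  asymptotic ceiling on held-out accuracy.

What the generator does **not** emulate: scanner/site effects, family
relatedness, missingness mechanisms, longitudinal growth, Likert
discreteness (by default), or non-linear brain-behavior structure. Passing
tests therefore demonstrate that the pipeline is correct and calibrated
under a linear-Gaussian world with known truth — not that any particular
real-data result is reproduced.

## Problem sizes used in validation

The simulation studies in the test suite and acceptance script use reduced
resampling (10-50 outer splits, a 4-point penalty grid, 3 inner folds) and
cohort sizes of n = 500 (calibration, 200 cells × 100 permutations),
n = 5,000 (accuracy/importance recovery and cross-sex contrasts, 10-20
seeds) and n = 600-800 (full 162-cell study runs at 20-50 splits with 100
permutations). These sizes give stable pass/fail behavior for the
properties being checked; production defaults (100 splits, 16-point grid,
1,000 permutations) remain the recommended settings for real analyses.

## Known limitations and open choices

- Exact row-order invariance of the resampling pipeline is impossible with
  position-based seeded splits (permuting rows jointly changes split
  membership); invariance holds distributionally and is tested with a small
  tolerance.
- The permutation scheme shuffles the behavior vector; label-swap or
  residual permutation schemes are not implemented.
- No covariate residualization (age, site) in the default path; a hook
  (`preprocess.residualize`) exists for sensitivity analyses.
- Parametric p-values for accuracy, spatial (spin/variogram) nulls,
  subcortical features, and nonlinear models are out of scope.
- Weight vectors are reported in standardized feature space; importance
  maps inherit that scale, which is immaterial for cosine comparisons.
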