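# Methods

This note documents the statistical machinery, the synthetic-cohort
generative model, the numerical choices, and the limits of what the test
suite demonstrates.

## Normative age models

Both "X-age" models share one engine (`devgap.age.NormativeAgeModel`):

1. **Training population.** Participants whose every clinical screening
   scale is strictly below 60 (the conventional non-clinical T-score range),
   after selecting one visit per participant uniformly at random.  Using a
   random timepoint from both waves widens the age range the model sees
   (9–13 rather than 9–11 years).
2. **Nested, family-grouped cross-validation.**  Families are shuffled and
   partitioned into the outer folds, so siblings are always co-assigned;
   outer test sets partition the training population exactly.  Inner folds
   (again family-grouped, on training data only) choose hyperparameters by
   mean absolute error.  All preprocessing — standardization, PCA — is
   refit inside each training fold; nothing from a test fold ever touches
   a fit.
3. **Estimators.**
   * `kernel_pca` (brain age): per-feature standardization, PCA retaining
     the smallest number of components whose cumulative explained variance
     reaches the threshold (default 0.90; constant features are dropped
     with a warning first), then RBF-kernel support-vector regression.
     Default grid: C ∈ {0.1, 1, 10, 100}, γ ∈ scale-heuristic × {0.1, 1, 10},
     ε ∈ {0.01, 0.1}.  The brain model pools sexes (one global accuracy is
     the relevant summary).
   * `additive_spline` (puberty age): an additive model with one smooth
     term per feature.  Continuous features get a clamped cubic B-spline
     basis (5 df, quantile interior knots); features with ≤ 5 distinct
     training values — the 4-level PDS ordinals, binary menarche — get a
     saturated indicator basis, since quantile knots degenerate there.
     All term coefficients share a single ridge penalty chosen from a
     log-spaced grid ({0.01, 0.1, 1, 10}) by the inner CV; the fit is a
     closed-form penalized least-squares solve, which keeps the
     replicate-heavy calibration studies cheap.  Puberty models are fit
     per sex (item sets differ; onset timing differs).  Hormones enter on
     the log scale.
4. **Final model.**  Refit on the full training population with the
   per-fold winning hyperparameters aggregated by mode (categorical) or
   median snapped to the grid (numeric) — deterministic and simple.
5. **Bias adjustment.**  Normative age predictions regress toward the
   training mean, so the raw gap ŷ − y has a negative age slope.  We adopt
   the residualization correction: fit ŷ − y = γ₀ + γ₁y on the training
   sample's out-of-fold predictions and subtract the fitted trend
   everywhere.  By least-squares orthogonality the adjusted gap is exactly
   uncorrelated with age in the training sample.  An alternative correction
   (rescaling predictions by 1/slope) exists and would change gap magnitudes
   slightly; the residualization form is preferred because it never touches
   test-side age labels beyond the already-needed covariate.
6. **Accuracy reporting.**  Pearson r and MAE (months) are computed on the
   *raw* out-of-fold predictions.  The RTM adjustment is a function of age
   alone: evaluating adjusted predictions against age would credit the
   model with information it did not predict (a constant predictor would
   score r ≈ 1), and would make permutation-null checks meaningless.
7. **Application.**  The fitted model is applied to the whole cohort,
   beyond the typically-developing group.  Rows belonging to the training
   population reuse their out-of-fold raw predictions (keyed by
   participant and visit), so no participant is ever scored by a model
   that saw them.

Missing data are handled by listwise deletion within each model's feature
set, with dropped counts logged.

## Association, contribution, mediation

* **Association** (`devgap.association`): `brain_gap ~ puberty_gap + age`
  with a site random intercept, maximum likelihood (ML rather than REML so
  AICs are comparable across puberty variants, whose fixed effects differ),
  fit with statsmodels MixedLM.  One participant per family is sampled
  first.  Within each sex the three variants are fit on identical rows.
  With fewer than 3 sites, a singular site variance, or a non-converged
  fit, the model falls back to OLS with a logged warning rather than
  failing — small synthetic cohorts must stay runnable.  Benjamini–Hochberg
  FDR is applied across the three variants within sex.
* **Contribution** (`devgap.contribution`): the brain-age model is
  retrained without one lobe (6 lobes: frontal, parietal, temporal,
  occipital, insular, subcortex) or one region/feature, with fold
  assignments and seeds held fixed so ΔT = T_full − T_without reflects
  feature removal, not resampling noise.  PCA is refit in each iteration
  at the same variance threshold, so the retained component count may
  differ.  ΔT values are not normalized and need not sum to T_full.  The
  Desikan-Killiany lobe assignment ships as a versioned JSON data file;
  the cingulate is split between frontal (anterior) and parietal
  (posterior/isthmus) by convention and the map is user-overridable.  At
  region granularity a "region" is hemisphere-specific with all its
  metrics dropped together; at feature granularity single region-metric
  columns are dropped — both readings of a single-region leave-out are
  exposed.
* **Mediation** (`devgap.mediation`): three mixed models per outcome scale
  (A: mediator on exposure; B: outcome on exposure + mediator; C: outcome
  on exposure), all with age, baseline outcome (unless disabled) and a
  site random intercept; exposure and mediator are baseline gaps, outcomes
  are follow-up scores.  ACME = a·b, ADE = model B's exposure term, total
  = model C's exposure term; in this linear system ACME + ADE = total up
  to numerical tolerance.  Inference: nonparametric bootstrap over
  participants (family duplication was already removed; site re-enters
  each refit), percentile 95 % intervals, p = doubled bootstrap tail
  floored at 1/n_boot.  Percentile rather than BCa intervals are used as
  the simplest defensible default.  FDR is applied across all scale ×
  effect cells within sex.  The bootstrap loop uses an internal
  profiled-ML random-intercept fitter (`devgap._lmm`): with a single
  random intercept the likelihood profiles to a 1-D search over the
  variance ratio with a closed-form GLS solve per evaluation; it is
  validated against statsmodels MixedLM in the test suite and makes
  1000-draw × 11-scale bootstraps a matter of seconds.

## The synthetic cohort

`devgap.simulate.generate_cohort` emulates a two-wave, multi-site,
sibling-containing early-adolescent cohort.  Per participant: a latent
pubertal-timing offset δ_p ~ N(0, 1 yr²); a latent brain-maturation offset
δ_b = β·δ_p + N(0, 0.5²) with β = 0.3 yr/yr by default, distributable
across lobes via nonnegative weights; PDS items generated by pushing a
logistic maturity curve of effective pubertal age (age + δ_p; onset 11 y
for girls, 12 y for boys, width 1.5 y) through fixed per-item thresholds
(yielding item means ≈ 1.5–3 over ages 9–13, an early-pubertal cohort);
menarche as a single monotone threshold draw; hormones log-normal in
effective age with a shared per-person assay-day factor; brain features on
region-specific linear-plus-quadratic trends evaluated at
age + w_lobe·δ_b + η, where η ~ N(0, 0.9² yr²) is subject-level
maturational noise shared across all regions.  η is what bounds attainable
brain-age accuracy, standing in for the strongly correlated morphometric
variance of real cohorts — without it, 218 weakly noisy features would
support near-perfect age prediction, which no morphometry-based model
achieves.  Site effects are additive feature intercepts proportional to
each feature's age slope (a scanner-offset analogy).  Follow-up
mental-health scores are 50 + 0.6·(baseline − 50) + path_b·δ_b +
path_c·δ_p + N(0, 6²) in T-score-like units (defaults path_b = 1.0,
path_c = 1.5); a separate set of screening scales with a shared problem
factor yields a typically-developing fraction near one half.  Missingness,
when requested, is MCAR over hormone/PDS/brain cells only — the analysis
drops incomplete rows, so informative missingness is out of scope.

Under these defaults the cross-validated accuracies land in the band
reported for real early-adolescent cohorts (raw out-of-fold r ≈ 0.7 for
brain and physical puberty age, ≈ 0.5 for hormonal; MAE 8–10 months), with
the characteristic ordering (hormonal weakest, combined ≥ physical).

What the generator does **not** emulate: non-Gaussian morphometric
distributions, regional covariance structure beyond one global factor,
informative dropout, menstrual-cycle or assay-protocol artifacts,
measurement invariance problems in parent-reported items.  Passing
recovery tests therefore demonstrates that the pipeline's statistics are
correct and well calibrated under a realistic signal/noise regime — not
that any particular real-data effect size will replicate.

## Numerical and design choices

* One top-level seed per run; every stage derives a named substream
  (SHA-256 of seed and stage name), recorded in the pipeline manifest;
  identical config + seed reproduces byte-identical output tables.
* `SimulationConfig` exposes `path_a` and `coupling_beta` for the same
  latent edge; `path_a=None` defers to `coupling_beta` so there is one
  source of truth.
* PCA component selection uses a 1e-10 slack on the cumulative-variance
  comparison so exact-boundary cases are stable; ties in grid search
  resolve to the earlier grid entry.
* Degenerate inputs: zero age variance fails the RTM fit; zero-variance
  outcomes yield flagged degenerate mediation results rather than errors;
  exactly collinear designs fall back to least-norm solutions.
* The demo pipeline configuration uses 5 outer / 3 inner folds and compact
  hyperparameter grids; the replicate-heavy calibration studies in the
  test suite use n = 500–2000 cohorts with 4–5 outer folds and one- or
  two-point grids.  These problem sizes are the package's choices for its
  own studies; the library defaults remain 10 × 10 folds with the full
  grids.

## Known limitations

* The additive-spline model treats ordinal PDS items as categorical
  (saturated) rather than ordinal-constrained; with four levels this
  costs little but does not enforce monotonicity.
* The mixed models use a single random intercept (site); family effects
  are handled by sampling rather than by nested random effects.
* Mediation assumes the linear two-equation system; no
  sensitivity analysis for sequential ignorability is provided.
* The contribution scan reports ΔT magnitudes only; no permutation
  significance is attached to them.
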