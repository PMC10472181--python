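# Methods

This note documents the models, defaults, and numerical choices behind
`trajphen`, and what the synthetic-cohort experiments do and do not show.

## Data model

The unit of analysis is a participant × mission adherence trajectory:
ratings on a 1–5 Likert scale at biweekly weeks 1, 3, …, 25 (13 points by
default; the grid is configurable because monitoring schedules vary between
studies). First and last observations are assumed present for analyzable
participants; interior cells may be missing. The outcome is a single
continuous number per participant (change in BMI z-score, post − pre), and
22 already-scored baseline covariates (demographics, anthropometrics,
psychosocial scales, lifestyle measures, attendance) form the adjustment
set.

## Synthetic cohort generator

`synthetic.generate_cohort` emulates that design with a two-mode latent
structure per mission:

x_i(t) = μ(t) + L_i φ_level(t) + T_i φ_timing(t) + ε_i(t),  ε ~ N(0, noise_sd²)

- μ(t): gentle logistic improvement from ≈2.85 to ≈3.6 on the Likert scale
  (baseline 2.8, gain 0.8, midpoint week 9) — typical of cohorts that start
  mid-scale and improve modestly.
- φ_level: constant, unit-norm on the domain (1/√24 on weeks 1–25). Its
  score L_i ~ N(0, level_sd²), level_sd = 1 by default: who is consistently
  high vs low.
- φ_timing: a logistic step centered at week 9 (configurable within the
  8–10-week window), time scale 1 week so the 12%→88% rise spans ≈4.4
  weeks; mean-centered (hence orthogonal to φ_level) and unit-normalized
  under the trapezoidal inner product on the observation grid. Its score
  T_i ~ N(0, timing_sd²), timing_sd = 0.6: late improvers (+) vs early
  adopters who fade (−).
- Scores are sampled independently per mission and exactly mean-centered,
  so the stored truth satisfies the zero-mean convention of FPCA scores.
- Ratings are the trajectory rounded half-away-from-zero and clamped to
  [1, 5]; observation noise_sd defaults to 0.3.
- Missingness is MCAR on interior cells (default rate 0.10); endpoints are
  never masked. Masked values are retained as a shadow copy so imputation
  error can be measured exactly.
- The outcome is linear in the 10 latent scores and 22 covariates plus
  N(0, 0.5²) noise. Default coefficients plant four nonzero score effects
  (M1 level −0.3, M2 timing +0.3, M3 level +0.3, M5 timing −0.3, in
  score units) and all-null covariates, giving standardized effects of
  roughly 0.43 (level) and 0.26 (timing) — comfortably detectable at the
  cohort sizes used here. Covariates are independent standard normals
  except a Bernoulli(0.7) male indicator, mirroring a 71%-male cohort;
  cross-covariate correlation is deliberately not modeled.

What the generator does **not** emulate: informative missingness (real
dropouts are likelier among less-motivated participants), cross-mission
correlation of adherence, floor/ceiling clustering of ratings, or
covariate–score dependence. Tests passing on these cohorts show the
machinery is correct under the stated model, not that the model captures
every feature of real adherence data.

## Preprocessing

Participants are excluded when their missing fraction — pooled over all
mission × week cells, matching a single global exclusion decision — is
strictly greater than 20%, or when any mission lacks its first or last
observation. A per-mission variant of the rule is available
(`per_mission=True`) because the pooled reading is an interpretation; the
pooled form is the default. Remaining gaps are filled by linear
interpolation **in week coordinates** (not index coordinates), so unequal
gaps are handled correctly; imputed values are convex combinations of the
bracketing observations and therefore always within [1, 5].

## Smoothing

Cubic B-splines (order 4) on an open-uniform knot vector over the
observation window; n_basis defaults to min(13, n_obs). The roughness
penalty is the integrated squared second derivative, with the penalty
matrix computed exactly by Gauss–Legendre quadrature per knot span (the
integrand is piecewise polynomial, so the rule is exact). λ is selected by
GCV, n·RSS/(n − tr H)², on a 25-point log grid spanning 1e−6…1e6, with ties
broken toward heavier smoothing. One λ per mission — the grid value nearest
the median log of the per-participant GCV picks — keeps curves comparable
across participants; the chosen value is recorded in every curve artifact.
Fitted curves are not constrained to [1, 5]: mild overshoot is the normal
behavior of linear smoothers and is inherited by FPCA, which operates on
the curves, not the ratings.

Degenerate cases: at λ = 0 a rank-deficient design raises rather than
silently picking one of many interpolants; at λ → ∞ the fit approaches the
least-squares straight line (second-derivative norm → 0).

## Functional PCA

FPCA is computed on curve values at a dense grid (default 101 points) under
trapezoidal quadrature weights w: with W = diag(w) and K the (n−1)-denominator
sample covariance matrix of centered curve values, the symmetric problem
W^{1/2} K W^{1/2} u = λu is solved by a dense symmetric eigensolver,
eigenvectors are back-transformed by W^{−1/2}, and ⟨φ, φ⟩ = Σ w φ² = 1 holds
by construction. Negative eigenvalues from roundoff are clipped at zero
before variance proportions. This grid-based route was chosen over
basis-coefficient FPCA because it is equivalent in the dense-grid limit and
directly checkable against an independent dense eigensolver.

Retention: smallest K with cumulative variance ≥ 70%, capped at max_k = 2
by default. The cap matters: realistic adherence spectra often need 3+
components to reach 70%, yet two interpretable modes (level, timing) are
the analysis target; when the cap binds, a warning reports the uncapped K
so the discrepancy is never silent.

Orientation: PC1 is sign-fixed so ⟨φ₁, 1⟩ > 0 (positive score = overall
high adherence); PC2 so its mean over the final third of the domain exceeds
its mean over the first third (positive score = late improvement); higher
components get a positive maximum-magnitude entry. Scores flip with their
eigenfunctions, so reconstructions are invariant. An exactly-zero
orientation statistic leaves the sign unchanged with a warning.

Perturbation displays use mean ± √λ_k φ_k, the standard "mean ± 1 SD of the
mode" visualization.

Eigenfunction agreement is measured by `grid_alignment`, the absolute
cosine under the quadrature inner product. Pearson correlation is undefined
against the constant level mode (zero variance), whereas the cosine is the
natural inner-product notion of agreement for unit-norm eigenfunctions.

**Quantization limitation.** On cohorts with the default settings
(noise_sd = 0.3), FPCA applied to the underlying continuous trajectories
recovers both generating modes with alignment ≥ 0.95 at n = 200 (≥ 0.99
noiseless). The 5-point Likert quantization, however, is a coarse
non-dithered rounding (step 1.0 vs noise SD 0.3) that systematically
distorts the second mode: through the full smooth-then-FPCA pipeline on the
rated panel, the level mode still aligns at ≥ 0.95 but the timing mode
typically reaches only ≈ 0.87–0.96. This is a property of the measurement
scale, not of the estimator, and it is why the pipeline-level test asserts
a weaker bound for the timing mode on rated data.

## Outcome model

Elastic net in the glmnet parameterization, (2n)⁻¹RSS +
λ[α‖β‖₁ + (1−α)/2‖β‖²], solved by cyclic coordinate descent
(scikit-learn's solver, with precomputed Gram updates). α is a fixed input
(default 0.01, near-ridge), never tuned. The λ path has 100 log-spaced
points from λ_max = max_j |x_jᵀ(y−ȳ)| / (n·max(α, 10⁻³)) down to 10⁻⁴λ_max.
CV uses seeded shuffled 10-fold splits; the λ minimizing mean squared
prediction error is kept (ties to the larger λ). Predictors are
standardized by sample mean and SD (n−1); the outcome is left on its
original scale by default, and standardized βs are reported via the
outcome SD. λ = 0 falls back to exact least squares.

Stability protocol, the literal two-stage reading of the repeated-CV +
bootstrap recipe: stage 1 repeats [CV-tune λ, refit on the full sample,
record the nonzero pattern] n_reps times (default 1000) with fresh fold
seeds, giving each predictor a survival fraction; stage 2 draws n_boot
(default 500) participant bootstrap resamples, re-tunes λ per resample
(a global-λ flag reuses the stage-1 median instead), and reports the
median and 2.5/97.5 percentile interval of each coefficient on both
scales. Selection is survival > 10%, strictly. The table reports bootstrap
medians and intervals for every predictor plus `reported_*` columns in
which non-survivors are zeroed — keeping both the "median unless it failed
to survive" reporting rule and the interval bracketing intact. The
model-level log-λ summary is the median over stage-1 repetitions; it is a
data-dependent quantity logged per run, never a constant.

**Operating-characteristic limitation.** Survival fractions are computed on
one dataset, so they are nearly 0/1 per predictor: across repetitions only
the fold split changes, and whether a coefficient is zero at λ_min is
almost a deterministic function of the data. Two consequences, both
verified against glmnet on identical data/folds/paths: (i) on pure-noise
cohorts the CV curve usually attains its minimum at the top of the path
(all-zero fit, survival ≈ 0), but in roughly a third of realizations it has
a shallow interior minimum, making every coefficient nonzero — so the
pure-noise characteristic is meaningful only as a typical-case (across
cohorts) statement; (ii) whenever detectable signal is present, λ_min is
small and the ℓ1 threshold αλ falls far below the null-gradient scale
σ/√n, so null predictors essentially always carry small nonzero
coefficients and the 10% survival rule does not control false selection at
these sample sizes. Effect sizes and bootstrap intervals, not survival
flags, carry the signal/noise distinction; the analysis drivers say so in
their output.

## Clustering

k-means (k = 4 by default, the 2×2 level × timing quadrant structure) in a
mission's (PC1, PC2) score plane: Lloyd's algorithm with k-means++
initialization, best of 50 seeded restarts by WCSS. Scores are clustered
unscaled — they already live on comparable, eigenvalue-weighted scales — with
a standardization flag available. Clusters are renumbered by descending
centroid PC1 then PC2, making the labeling deterministic across restarts
and runs. k itself is a modeling choice; a silhouette scan over k = 2…8 is
provided as a report, not an automatic selector. Profiles are contingency
tables of caller-supplied category rules (e.g. age < 12) with counts and
within-cluster percentages.

## Pipeline and reproducibility

`run_all` chains simulate/load → preprocess → smooth → FPCA → fit → cluster,
persists every intermediate artifact (long-format adherence CSV with empty
cells for missing, JSON curve stores, CSV score/coefficient tables), and
derives each stage's seed from the master seed with a counter-based
spawn-key scheme, so adding a stage never shifts earlier streams. Identical
config + seed reproduces every output byte for byte; failures abort with
the stage name while keeping prior artifacts on disk.

## Problem sizes used in the checks

The demonstration cohort is 120 participants; recovery experiments use
n = 200 (eigenfunctions) and n = 500 (coefficients); the stability protocol
is exercised at 200 repetitions / 100 bootstraps, which resolves survival
fractions to 0.005 and leaves percentile intervals stable, with the full
1000/500 protocol available through configuration.
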