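# Methods

This note documents the statistical model, the estimation machinery, the
synthetic-data generator and the numerical and design choices behind
`vcunet`, at the level of detail a maintainer or reviewer needs to judge
what the package's results do and do not show.

## The analysis model

The unit of analysis is the variety-by-trial adjusted mean — the output
of a first-stage, within-trial analysis that is assumed done upstream.
The second stage is unweighted: no trial-level precision weights are
carried, because the historical archives this package targets do not
provide error mean squares per trial and trait. The price of the
two-stage shortcut is that the plot error (divided by the within-trial
replicate count) is confounded with the three-way
genotype-location-year interaction in a single term GLY'. That
compounding limits biological interpretation of the three-way
interaction but not the precision arithmetic, because GLY and plot error
enter every SED formula through the same 1/(n_L·n_Y) factor: the
plot-level expression

    sed^2 = 2( s2_GL/n_L + s2_GY/n_Y + s2_GLY/(n_L n_Y) + s2_eps/(n_L n_Y n_R) )

collapses exactly to the two-stage expression with
s2_GLY' = s2_GLY + s2_eps/n_R (an identity the test suite checks to
1e-12 over random component draws).

Model variants:

* **univariate** (one country, one trait): fixed intercept, trial-year
  trend gamma, maturity-group means, FYOA trend beta; random L, Y, LY,
  G, GL, GY, maturity-by-environment terms and the GLY' residual.
  Layouts differ in bookkeeping: the AT-style layout has no subtrials
  and carries ML and MY; the FR-style layout nests maturity groups in
  subtrials within trials — maturity is then fully confounded with
  subtrial, so S(LY) enters and ML/MY are dropped.
* **bivariate** (two traits): trait-specific fixed effects and
  environmental variances; unstructured 2x2 covariance across traits for
  G, GL, GY and GLY' (the residual pairs records of the two traits from
  the same variety and trial). The genotypic trait correlation rho_G is
  tested by a 1-df likelihood-ratio test of rho_G = 0, with
  Benjamini-Hochberg correction across trait pairs.
* **combined** (two countries, one trait): country-specific fixed
  effects and variances, a genetic trend shared across countries, and
  unstructured 2x2 covariance across countries for G, Y and GY. Every
  base level (e.g. a variety) carries a latent effect in *both*
  countries even when observed in one, which is what lets a merged
  analysis predict a variety's performance in a network that never
  tested it.

Protein content is stored as a fraction and logit-transformed before any
fit; trends, LSDs and adjusted means are back-transformed by the delta
method (derivative mu_p(1-mu_p) at the fitted intercept).

## REML engine

Estimation maximizes the restricted likelihood through Henderson's
mixed-model equations (MME); `log|V|` and `log|X'V^-1X|` are obtained
together as `log|R| + log|G| + log|C|` from one factorization of the MME
coefficient matrix C. Three performance layers keep study-sized
problems (≈2,000–5,000 records, ≈1,500–4,000 effect levels) at a few
seconds per fit on one core:

1. **Sparsity.** C is assembled from per-residual-group Gram matrices
   precomputed once; each likelihood evaluation only rescales and
   refactorizes (sparse LU, minimum-degree ordering).
2. **Absorption.** Every non-correlated random term has a *diagonal*
   block in C (a record loads on exactly one of its levels). The largest
   such term — typically GL — is eliminated analytically by a Schur
   complement, shrinking the factored core by up to two thirds.
3. **Average information.** For models with a diagonal or paired-2x2
   residual, the REML scores are computed exactly from block traces of
   the inverse coefficient matrix (via Z'PZ = G^-1 - G^-1 C^uu G^-1 and
   tr(PV) = n - p), and the average-information matrix from working
   vectors V-dot @ Py, each costing one MME solve. Newton steps with a
   trust-region cap and step halving converge in ~10 iterations;
   variances collapsing to zero are pinned at a small floor (reported as
   zero-bounded) and released if their score turns positive again. The
   inverse AI matrix at convergence doubles as an approximate sampling
   covariance of the variance parameters.

Small problems (fewer than ~450 MME columns) instead use a quasi-Newton
search on log-variances and atanh-correlations, a derivative-free
simplex polish, and an exact EM fixed-point refinement, which pins the
optimum to ~1e-13 — this is what lets the balanced-case tests demand
agreement with closed-form ANOVA estimators to 1e-8, beyond what any
likelihood search can resolve in floating point.

Any subset of components and correlations can be frozen at given values;
this single mechanism serves the zero-correlation counterfactual in
network merging, constrained fits for likelihood-ratio tests, and
"solve-only" uses of the MME (heritability and SED computations at known
components). Convergence is declared on relative likelihood change
< 1e-9 together with relative parameter change < 1e-7 (AI path) or the
optimizer's own criteria plus the EM fixed point (search path);
non-convergence flags the result rather than raising.

Fixed-effect designs are built full-rank by construction (drop-first
coding, within-group dropping for nested means) and verified by a rank
check that names aliased columns. In the fixed-variety variant used for
adjusted variety means, both the FYOA covariate and the maturity means
are linear combinations of the variety dummies and are therefore
excluded.

## Heritability, precision, trends

* **Cullis H2** uses the average variance of a BLUP difference over all
  variety pairs, computed from the genotypic block of C^-1 as
  (2/m(m-1))((m-1)·tr - (sum - tr)). On balanced designs it equals
  s2_G/(s2_G + s2_GL/n_L + s2_GY/n_Y + s2_GLY'/(n_L n_Y)) to machine
  precision (verified to 1e-6 in the tests); values outside [0,1] are
  clamped with a warning.
* **LSD** defaults to the multiplier 2 (the usual approximation of
  t_{alpha/2}); the exact t quantile is available given error degrees of
  freedom. LSD% divides by the empirical 0.95 quantile of the
  variety-by-trial means for that country and trait, computed with the
  linear-interpolation convention on the raw (back-transformed) scale.
  The reference distribution behind Q0.95 is a documented choice — raw
  trial means per country and trait — since alternatives (variety means,
  per maturity group) are equally defensible.
* **Trends.** beta (on FYOA) and gamma (on trial year) are jointly
  identifiable because varieties are tested in several calendar years.
  Significance uses a t reference with Satterthwaite denominator degrees
  of freedom computed from the average-information covariance of the
  variance parameters. The plug-in Wald z test is anti-conservative here
  (7.5-9% empirical size at nominal 5% over 200 simulated networks),
  because in a non-trivial fraction of datasets the year variance is
  estimated at its zero boundary, which deflates the trend's standard
  error; the Satterthwaite t restores calibration (3.0% in the same
  experiment), while a fixed t with (years - 2) df over-corrects
  (1.5-2.5%). Relative trends divide by the model-predicted mean at the
  reference year (averaged over maturity groups); protein-content trends
  are back-transformed before forming the ratio.
* **CV convention.** CVs are 100·sd/intercept on the analysis scale;
  for protein content the ratio uses the magnitude of the logit-scale
  intercept. This is the only convention that makes the set of reported
  quantities for a logit-analysed trait (CV near 15-20%, G-share near
  75%, LSD% near 2%) mutually consistent; the delta-method raw-scale CV
  (a few percent) is available separately
  (`cv_percent_backtransformed`).

## Network merging

The merge computation freezes components and correlations at the
combined-model estimates and assembles the MME for a constructed, fully
balanced design: by default 10 locations, 2 years and 10 varieties per
membership class (both networks / only network 1 / only network 2) per
country, each variety in all of its network's trials. Pairwise SEDs of
the *random genotypic effects* come from the G block of the generalized
inverse of the coefficient matrix; they are deliberately not the Eq.-type
SEDs of adjusted means used in the single-network precision section, and
the two pathways are never mixed in one report. Averages over variety
pairs within each of the eight membership/focal scenarios, normalized by
the focal network's Q0.95 and multiplied by 2, give the scenario LSD%;
the counterfactual zeroes rho_G, rho_Y and rho_GY, and the improvement
is the difference in percentage points.

Choices where the design was open: the constructed design uses a single
maturity group per country (cross-country maturity labels are not
harmonizable), making M, ML, MY, MLY and S(LY) level-wise redundant, so
they are omitted from the frozen-component MME; the shared genetic-trend
covariate is dropped because r_i = 0 for all constructed varieties (the
comparison is between varieties, not cohorts); replicate rows are
collapsed to variety-by-trial means when the components come from a
two-stage fit, since s2_GLY' already contains the plot error divided by
the replicate count; a correlation estimated at ±1 is represented as
±(1 - 1e-6) to keep the genetic covariance invertible; when the year
correlation cannot be estimated (as happens for protein content), the
merge should be run with rho_Y frozen at 0 and flagged — conservative,
in that it foregoes any year-level information sharing.

Two identities anchor the implementation: with all cross-network
correlations zero, scenarios (i, iii) and (ii, vi) coincide exactly in a
balanced design, and activating positive correlations never increases
any scenario's LSD%. Note that at rho = 1 with equal variances the two
focal networks' SED matrices coincide, but a cross-network pair does
*not* reach the SED of a jointly tested pair: the contrast still carries
the uncertainty of the country-intercept difference, and a variety
tested in both networks simply has twice the data.

## Synthetic-data generator

The generator is first-class, tested code, and its defaults are the
study conditions: 16 trial years from 2003; 8 (AT-style) or 10
(FR-style) locations per year; two-year test cycles with annual cohorts
(5/year AT, 1/year FR) plus persistent checks (6 and 3, reproducing the
observed median between-year variety overlaps of ~6 and ~3); 2 maturity
groups (AT) or 4 nested in subtrials (FR); and variance magnitudes
chosen so that the derived summaries land in the reported ranges —
genotypic CVs near 5% for yields, GEI CVs of 2.5-3.5% (GL, GY) and
7-9% (GLY'), genotypic trends near 2%/yr (AT) and 0.9%/yr (FR), and
protein-content components on the logit scale (s2_G ≈ 0.005,
i.e. a genotypic SD of ~1.8 percentage points of content around a 40%
mean). The dual-network generator draws G, Y and GY bivariate-normal
across countries (defaults rho_G = 0.85, rho_Y = 0.6, rho_GY = 0.7) and
shares 15 varieties between networks — the reported between-country
overlap, and empirically the level at which the cross-network genotypic
correlation becomes reliably estimable from a single realization.

Determinism contract: one named substream per model term, split from the
master seed, so adding or resizing one term never perturbs another
term's draws; the same seed reproduces a dataset bit-for-bit. Degenerate
2x2 covariances (rho = ±1, zero variances) use an exact analytic
Cholesky factor.

What the generator does *not* emulate — and hence what passing tests do
not show about real archives: spatial field trends and non-normal trait
distributions; heterogeneous plot-error variances across trials;
variety-ageing effects (varieties leave after two years, so the genetic
trend is a cohort effect, and trends estimated from such data can be
biased upward relative to designs that retest old varieties);
location sets that drift over years (locations persist here);
registration-date measurement error in FYOA beyond what turnover
induces; and missing-data mechanisms other than the occurrence structure
itself.

## Validation experiments shipped as tests

* Balanced one-way and two-way REML equals ANOVA method-of-moments to
  1e-8 (via the EM fixed point); the one-way fit also cross-checks
  against an independent mixed-model implementation.
* The REML optimum matches a dense grid search over an independently
  coded restricted likelihood on a 20-observation toy.
* Parameter recovery at study size (16 years, 8 locations, ~300
  varieties, 100 replicates): each component's 95% interval covers its
  generating value in at least 90 replicates. Intervals are Wald on the
  log-variance scale from the AI covariance; borderline cases
  (|z| between 1.6 and 2.4) are resolved by the exact profile
  likelihood-ratio criterion with a constrained re-fit, since Wald
  intervals are the standard large-sample approximation to profile
  intervals but can be slightly narrow for heavily shrunk components.
* Trend calibration: type-I error of the gamma test within 3-7% and
  beta CI coverage ≥ 90% over 200 simulated networks.
* The LSD identities, grid monotonicity, merge identities and
  information inequality described above.

Problem sizes in the simulation experiments (replicate counts, the
smaller networks used for the 200-replicate calibration) were chosen to
give the binomial checks adequate resolution while keeping the whole
suite runnable in a routine development cycle.

## Known limitations

* Unstructured covariance blocks are limited to two groups (two traits
  or two countries); a trivariate analysis must be decomposed into
  pairs.
* The AI path requires a diagonal or paired-2x2 residual; exotic
  residual structures would fall back to the derivative-free search.
* Standard errors for variance parameters come from the AI matrix and
  are asymptotic; for components supported by few levels (location and
  year main effects in a 16-year network) profile intervals are
  noticeably asymmetric and the Wald numbers should be read as rough.
* The merge computation assumes both networks sample the same trait
  scale and environment distribution; systematic country differences
  beyond the modelled fixed effects (management regimes, elevation
  gradients) are not represented.
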