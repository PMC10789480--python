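# Methods

## The statistic

For a participant and brain state, let `z_ij = atanh(r_ij)` be the
Fisher-transformed Pearson correlation between the denoised signals of ROIs
i and j. Given a partition of ROIs into large-scale networks with a binary
*associative* flag per network, define over the unordered pairs whose two
ROIs both lie in associative networks:

- `W` — mean of `z_ij` for pairs in the same network,
- `B` — mean of `z_ij` for pairs in different networks,
- `SyS = (W − B) / W`.

Negative edges are zeroed before averaging (global signal regression induces
spurious negative correlations; zeroing them bounds SyS above by 1 and keeps
W > 0 interpretable). Means are unweighted over edges, not size-balanced
over networks; the alternative would up-weight small networks and is easy to
add, but edge-weighted averaging is the common convention for this statistic
and is what we test against the brute-force oracle. `W = 0` raises an error
rather than returning 0 or NaN — a silent 0 would masquerade as "no
segregation" when the statistic is simply undefined.

Associative–sensory pairs are excluded entirely under the default
`associative_only=True`: they enter neither W nor B.

## Denoising model

ROI signals are the first temporal eigenvector of their voxel block (sign
aligned with the voxel mean; the plain average is a near-equivalent
summary). Denoising is a single least-squares projection onto a joint
design:

- intercept;
- discrete-cosine drift basis with frequencies `k/(2·T·TR) < 0.01 Hz`
  (the high-pass filter as regressors, so filtering cannot be undone by a
  later step);
- 36 confound columns: nine base signals (six realignment parameters,
  white-matter mean, CSF mean, global mean) each entered raw, as a backward
  difference (first element 0), squared, and as a squared difference;
- one delta column per high-motion frame. The motion score is the RMS
  across the six linearly detrended realignment columns per timepoint;
  frames with score above `mean + k·SD` (k = 5 by default) are flagged.
  The "deviates more than 5 SDs" rule admits more than one reading; this
  one is recorded here and k is configurable.

Sequential filtering-then-regression can reintroduce removed variance; the
joint projection is unambiguous and makes the residuals exactly orthogonal
to every retained design column (checked to 1e-8 in the tests). Rank
deficiency is handled by dropping dependent columns with a warning.

The optional autocorrelation correction scales `atanh(r)` by
`sqrt(T_eff − 3)/sqrt(T − 3)`, with the Bartlett-style effective sample size
`T_eff = T / (1 + 2·Σ_k w_k ρ_i(k) ρ_j(k))` using a Tukey (cosine) taper
over lags up to T/3. White-noise series give `T_eff ≈ T`, leaving the plain
transform unchanged. This is a documented stand-in for unspecified package
internals in the literature this pipeline follows, and plain `atanh` is the
default everywhere.

The partial-correlation variant standardizes the series, shrinks the
covariance toward a scaled identity (Ledoit–Wolf intensity by default, any
fixed value in [0, 1] accepted), inverts, and standardizes the precision
matrix to correlation scale. With two ROIs and zero shrinkage it reduces to
the Pearson correlation; with shrinkage 1 all edges vanish.

## Statistical models

**Composites.** Cognitive batteries are reduced to the first principal
component of the column-standardized scores, rescaled to unit SD, sign
aligned with the row mean.

**Age models.** `outcome ~ age¹ + age² + sex + age¹:sex + age²:sex
[+ covariate (+ its interactions with age and sex, incl. three-way)]`.
The default age basis is the sample-orthogonalized degree-2 polynomial,
which makes the age terms invariant to shifting/scaling raw age; a
`standardized` basis (z-age and its standardized square) is available and,
with supplied population moments, exactly matches the synthetic generator's
planted basis — the correct estimand definition for recovery simulations,
since sample-moment standardization adds scale noise the CIs do not model.
Sex is effect-coded ±0.5; outcome and continuous predictors are z-scored by
default so coefficients are standardized betas. Partial η² is computed by
type-III-style term drops, `(SSE_reduced − SSE_full)/SSE_reduced`, which for
1-df terms equals `t²/(t² + df)`.

**Robust refits.** Huber IRLS with tuning constant 1.345 on residuals
standardized by the normalized MAD, convergence at max coefficient change
< 1e-8 or 50 iterations (non-convergence flagged, not silent). The
implementation is cross-checked against statsmodels' RLM in the tests. Note
the Huber = OLS identity holds only when every standardized residual stays
below the tuning constant; with unbounded (e.g. Gaussian) noise the two
estimators differ slightly even without outliers, which is expected
behaviour, not error.

**Mediation.** Product of coefficients on z-scored x, m, y with covariates
in every equation: `m ~ x + cov` (a), `y ~ x + m + cov` (b, c′),
`y ~ x + cov` (c). Indirect effect a·b; percent mediated 100·a·b/c, flagged
undefined when |c| < 1e-10; Sobel Z with the first-order SE
`sqrt(a²se_b² + b²se_a²)`; percentile bootstrap over cases with a fixed
seed (default 5000 reps). This product-of-coefficients estimator reproduces
the indirect/total-effect semantics of SEM-based mediation without a
structural-equation dependency. Because all three equations are OLS on the
same complete cases, `c = c′ + a·b` holds to machine precision — asserted
at 1e-10 throughout. No multiple-testing correction is applied anywhere,
mirroring the analysis convention this pipeline follows; users testing many
states/outcomes should correct externally.

Large-scale null calibrations use the Sobel p-value (500 simulated cohorts
run in seconds); the bootstrap CI is exercised at smaller replication
counts. Both are asymptotically conservative-to-nominal under a single null
path.

## Synthetic cohort: what it emulates, and what it does not

`generate_covariates` plants a linear structural model on standardized
variables: age uniform over (18, 88) — z-scored by its population moments,
with the quadratic basis `q = (z² − 1)/√0.8`, unit-variance and orthogonal
to z under uniformity — a latent SyS per state
`β_age1·z + β_age2·q + β_MA·MA + ε`, and cognition
`β_age·z + β_SyS·sys_rest + β_c′·MA + ε`. Sub-test scores load on latent
cognition with independent noise. Default magnitudes: a strong accelerating
age decline (β_age1 = −0.6, β_age2 = −0.15, echoing the large age effects
reported for this statistic over the adult lifespan), a null activity → SyS
path (β_MA = 0, the empirically typical case), moderate SyS → cognition
(0.3) and direct activity (0.2) paths, residual SDs 0.7. Path magnitudes
are user-set by design — the mediation literature this emulates reports
mostly null a-paths, so there is no empirical magnitude to copy.

The standardized latent maps to the (0, 1) fraction scale used as a
time-series target via `0.6 + 0.08·latent`, clipped to [0.02, 0.98] —
centering the simulated SyS distribution in the empirically typical range.

`generate_timeseries` draws multivariate Gaussian series from an exact
block correlation matrix (within w, between b, positive-definiteness
verified by eigenvalue check and failed loudly, never repaired silently),
so the population SyS has the closed form `(atanh w − atanh b)/atanh w` and
`sys_target_to_between_corr` inverts it as `b = tanh((1−s)·atanh w)`.
Confounds are injected *additively and linearly* through random per-ROI
loadings — deliberately, so that ideal confound regression removes them
exactly and the denoising stage has an analytic correctness check. Spikes
displace both the motion parameters and the ROI signals, with frames
recorded.

Consequently the generator does **not** emulate: hemodynamic response,
1/f or physiological noise spectra, nonlinear or delayed confound coupling,
heteroskedastic edges, site effects, or non-Gaussian tails. Passing tests
show the estimators are correct under the assumed model, not that the
pipeline is robust to real fMRI artefacts beyond that model.

All randomness descends from one seed through per-participant streams
(`default_rng([seed, participant, salt])`), so participant i is bit-identical
regardless of cohort size, and identical configs reproduce identical
outputs byte for byte.

## Problem sizes and numerical choices

Validation simulations use sizes at which Monte-Carlo error is comfortably
inside the asserted tolerances while the whole suite stays fast: 20 seeds ×
T = 5000 for closed-form pipeline recovery (tolerance 0.02), 100 cohorts of
n = 600 for CI coverage (≥ 90 of 100), 500 cohorts for rejection-rate
calibrations (binomial SE ≈ 1% at nominal 5%), n = 10000 for the planted
percent-mediated check (tolerance 2 points around 50%). Degenerate inputs
fail with typed errors naming the offending field, ROI or column; ties and
sign conventions (eigenvector signs, effect coding) are fixed explicitly so
reruns are bit-identical.

## Known limitations

- Voxel-level preprocessing (motion correction, normalization, smoothing)
  is out of scope; inputs begin at ROI time series or matrices.
- Robust-fit standard errors use the final IRLS weights (a common
  approximation), adequate for the outlier-sensitivity checks they support,
  not for formal robust inference.
- The autocorrelation-corrected z is a documented approximation, not a
  claim of equivalence to any specific package's internals.
- Mediation assumes linear, homoskedastic relations and no
  exposure–mediator interaction; no latent-variable or moderated mediation.
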