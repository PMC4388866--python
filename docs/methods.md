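# Methods

## Model

Counts follow a negative binomial, `Y_ij ~ NB(mu_ij, phi_ij)` with
`Var(Y) = mu + phi mu^2` (size `1/phi`; `phi -> 0` is the Poisson limit,
taken by an explicit branch below `phi = 1e-10` to avoid Gamma-function
overflow).  The mean model is log-linear with known offsets,
`log mu_ij = log(N_j R_j) + sum_k beta_ik X_jk`; library sizes `N_j` and
normalization factors `R_j` are accepted as given (`R_j = 1` by default) —
no normalization estimation is performed.  Two-group comparisons use an
intercept plus a group-2 indicator, so `beta_2` is the natural-log fold
change and the DE null hypothesis is `beta_2 = 0`.

Log dispersion decomposes into a trend in log relative abundance plus a
gene-level residual:

```
log(phi_ij) = f(log pi_ij; alpha) + eps_i,   eps_i ~ N(0, sigma^2) iid.
```

`sigma` is the package's central quantity: the residual dispersion SD a
fitted trend leaves unexplained.

## Fitting machinery

**IRLS.**  The mean model at fixed dispersion is fitted by iteratively
reweighted least squares, vectorised over genes (weights
`mu/(1 + phi mu)`), converged when the relative log-likelihood change
falls below `1e-8` or after 50 iterations, and reported as non-converged
otherwise (all-zero genes are the canonical degenerate case: fitted means
go to zero with a non-converged flag).  When the design rows and offsets
take exactly `p` distinct values and the dispersion is constant within a
gene — every two-group layout with equal offsets, and all the simulations
here — the score equations force the cell means to be the MLE for *any*
dispersion, and the closed form replaces IRLS.  This is what makes the
grid-heavy estimators below cheap.

**Genewise dispersion.**  One-dimensional profile-likelihood maximization
over `log phi in [-18, log 1000]`, by bounded Brent for a single gene or
by a shared grid (step 0.2) with 3-point parabolic refinement when
vectorised.  Boundary maxima are returned as `phi = 0` (underdispersed
data).  A Cox-Reid variant subtracts `0.5 log det(X'WX)` (the adjusted
profile likelihood, APL); the DE-testing layer uses it because the plain
MLE is biased low when mean parameters are estimated.

**Trends.**  `common`, `nbp` (log-linear) and `nbq` (log-quadratic)
trends maximize the summed APL over genes via Nelder-Mead, on a predictor
centred at the mean fitted log relative frequency (one geometric-mean
`pi_hat` per gene from a Poisson prefit).  Centring is stored on the
fitted trend, so parameterizations are comparable after recentring.  The
`smooth` trend bins genes by abundance (about 100 genes per bin, 4–25
bins), maximizes each bin's summed APL over a common log dispersion, and
interpolates the bin maximizers linearly with flat extrapolation beyond
the fitted range.  Binned shared-likelihood fitting was chosen over
smoothing individual genewise estimates because those estimates are
biased and extremely noisy at typical replicate numbers; smoothing them
produced a measurably miscalibrated trended test, while pooled bins do
not.

**Tagwise shrinkage.**  Per gene, `APL_i(phi) + G0 * APL_S(phi)` is
maximized on a shared log-phi grid, where `APL_S` is the average APL of
the 50 genes nearest in average log-cpm, translated in log-phi so that
its maximizer sits at the gene's trend value (anchoring reconciles the
windowed-average prior with the requirement that infinite prior weight
return the trend).  The default prior weight is `G0 = 10`.

**Quasi-likelihood.**  With trend NB dispersions `omega_i`, the residual
deviance `D_i` over `d_i = n - p` degrees of freedom gives the mean
residual deviance `s_i^2`.  Across genes `s_i^2 ~ s0^2 F(d_i, d0)`;
`(s0^2, d0)` are moment-matched (mean and variance of `s^2`, with a
log-scale digamma/trigamma variant available for heterogeneous `d_i`;
zero excess variance yields `d0 = inf`).  An optional correction reduces
`d_i` by the per-gene fraction of zero counts (off by default).  The
shrunk quasi-dispersion `(d0 s0^2 + d_i s_i^2)/(d0 + d_i)` scales the
deviance-difference F statistic, referred to `F(1, d0 + d_i)`.

## Estimating sigma

For gene `i` with trend prediction `theta0_i = log phi0_i`, the
conditional log-likelihood `l_i(eps)` re-maximizes the mean parameters at
`phi = exp(theta0_i + eps)`.  The marginal likelihood of `sigma^2`
multiplies, over genes, the integrals of `exp(l_i(eps))` against the
`N(0, sigma^2)` density; each integral is approximated by Laplace's
method at the mode `eps_i*` of `g_i(eps) = l_i(eps) - eps^2/(2 sigma^2)`:

```
log term_i = g_i(eps_i*) - 0.5 log(sigma^2 (-l_i''(eps_i*) + 1/sigma^2)).
```

The approximation is exact for quadratic `l_i` and agrees with adaptive
quadrature to about `1e-2` on realistic genes (checked in the tests).

Numerics: `l_i` does not depend on `sigma`, so it is tabulated once per
gene on an eps grid (`[-10, 10]`, step 0.25; one vectorised fit per grid
point) and interpolated with cubic splines; per-sigma work is a
warm-started vectorised Newton search for the modes (golden-section-style
fallback steps when curvature is not negative, and trapezoidal quadrature
on the tabulated grid for the rare genes whose integrand is not concave
at the candidate mode).  `sigma` is maximized by bounded Brent on the log
scale over `[1e-3, 5]` (tolerance `1e-4`); a maximum at the lower bound
is reported as `sigma_hat = 0` with an undefined standard error.  The SE
comes from the numerical observed information (central second difference)
of the profile log-likelihood at the maximum.

By default the tabulated `l_i` is the **Cox-Reid adjusted** conditional
likelihood.  The adjustment is itself a Laplace approximation — to
integrating the mean parameters out — and so treats `beta` and `eps`
consistently.  With the unadjusted profiled likelihood (`adjust=False`),
`sigma_hat` acquires a positive floor of roughly 0.2 at seven replicates
even when the generative `sigma` is zero, because profiling overstates
the per-gene evidence about `eps`; the adjusted form removes that floor
(estimates below 0.1 at `sigma = 0`, near-unbiased recovery across
`[0.3, 0.9]`).

Two further knobs are deliberate:

- `recenter` (default off) shifts the prior means so the eps modes
  average to zero.  A fitted trend's level is confounded with the
  residual mean, and a level offset inflates `sigma_hat^2` by its square;
  recentring removes this almost entirely.  It is off by default because
  the calibration step (below) is designed to absorb exactly this
  inflation, and the bias profile of the uncentred estimator is the one
  the accuracy study characterizes.
- `subsample` restricts estimation to a random gene subset for very large
  matrices.

**Accuracy study.**  `accuracy_simulation` simulates single-group data
(5000 genes and 7 replicates by default; the tests use 2000 genes) with
log-normal baseline means (mean 8.5, SD 1.5 on the log scale), a known
trend (log-quadratic by default, constant optionally), and
`N(0, sigma^2)` residuals at a ladder of sigma values, three replicates
each, then re-estimates sigma with the generative trend supplied.  The
generative trend — rather than a per-dataset refit — isolates the
estimator's own bias; refitting adds the trend-estimation inflation that
calibration corrects.  Median recovery is within a few hundredths across
`[0.3, 0.9]` and degrades at 0.1 (relative noise, boundary) and 2.0
(Laplace error in the far tails).

**Calibration.**  Real-data estimation uses fitted `pi_hat` as the trend
predictor, while generation uses true `pi`; together with estimator bias
this shifts `sigma_hat` away from the generative value.  The calibration
simulates datasets from the fitted template at a sigma ladder (default
0.5–1.5 in eight levels, three replicates), re-runs the full
trend-plus-sigma pipeline on each, fits a quadratic to the per-level
median estimates, and intersects it with the horizontal line at the
real-data `sigma_hat`; the abscissa is the calibrated `sigma_tilde`.
The 95% interval intersects the OLS prediction band with the same line.
The band is a single-observation interval — the observed `sigma_hat` is
one realization, not a median — and its residual scale pools all
replicate deviations around the fitted curve (`K * reps - 3` degrees of
freedom), because the medians-only residual with a five-level grid leaves
two degrees of freedom and collapses sporadically.

## Simulator

`simulate_two_group` draws `Y_ij ~ NB(mu_ij, phi_ij)` with
`log mu_ij = log N_j + beta_i1 + beta_i2 1{group 2}` and dispersions from
the trend evaluated at the **true** `pi_ij = mu_ij / N_j` (including the
DE effect) plus `N(0, sigma^2)` residuals.  A fraction `pi1` of genes is
designated DE; fixed fold changes place exactly half the DE genes up and
half down, or an explicit per-gene `beta_2` vector is used (matched to
the same genes by default, permutation optional).  One root seed expands
into independent streams for baseline means, DE designation, residuals
and count draws, so varying sigma leaves the DE designation untouched —
required for clean factorial comparisons.  Defaults: 5000 genes, depth
2.5e7, baseline log means `N(8.5, 1.5)`, NBQ trend
`alpha = (-3.2, -0.35, 0.05)` on the centred predictor.  The trend level
corresponds to a biological CV of about 0.2 at the median abundance — a
human-cell-line regime — rising toward low abundance; residual SDs near 1
match what the estimator reports on real datasets of this kind.

What the generator does *not* emulate: outlier counts, correlated genes,
GC/length biases, varying library sizes within an experiment, or
non-normal residual distributions.  Passing tests therefore demonstrate
internal consistency of the method under its own assumptions, not
robustness to those features of real data.

## DE test battery and evaluation

Six strategies share the same fitting core and differ only in the
dispersion plugged into the per-gene two-group test: genewise (CR-APL
maximizer), common, NBQ, trended (smooth), tagwise (G0 = 10), each with
the likelihood-ratio test against chi-square(1); and the QL F-test with
smooth-trend `omega_i`.  The genewise strategy here uses the plain LRT
with CR-adjusted dispersions; the small-sample higher-order adjustment
used by its published counterpart is out of scope, and the plain-MLE
variant is markedly anticonservative below about ten replicates per
group — the method-comparison tests therefore run at ten per group,
where the chi-square approximation is adequate while the trend-only
methods' miscalibration (which is structural, not a sample-size artifact)
remains fully visible.

Evaluation: BH step-up q-values (all-zero genes carry `p = q = 1` and are
excluded from the BH denominator), TPR/FDR curves along the p-value
ranking (ties broken by |logFC| then gene index; FDR undefined at zero
discoveries), actual FDR at a nominal level, KS-against-uniform and
20-bin histograms for null p-values, and MA values
(`A` = mean log2 cpm, `M` = log2 fold change).

## Problem sizes and determinism

The test suite and the acceptance script use 2000-gene simulations, three
replicates per condition and reduced calibration grids (five levels);
these sizes give stable medians for every property checked while keeping
the whole suite in the minutes range.  All stochastic procedures are
driven by explicit seeds through `numpy.random.SeedSequence` spawning, so
reruns are bit-reproducible.

## Known limitations

- `sigma` is assumed constant across genes; a mean-dependent residual SD
  would be absorbed into an average.
- The normal model for `eps` is a convenience; heavy-tailed residuals
  (outlier genes) would inflate `sigma_hat`.
- The QL shrinkage formula is the standard posterior-mean form; published
  implementations differ in detail (spline prior on the trend, df
  refinements for zeros).
- Table-style real-data quantities require the corresponding external
  datasets; the package validates the machinery on synthetic data with
  known truth.
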