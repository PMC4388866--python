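"""Estimation of the residual dispersion variance sigma^2.

A fitted dispersion trend leaves per-gene residuals on the log scale::

    log(phi_ij) = log(phi0_ij) + eps_i,     eps_i ~ N(0, sigma^2) iid,

where ``phi0`` is the trend prediction (treated as known).  The marginal
likelihood of sigma^2 integrates each gene's conditional profile
likelihood ``l_i(eps) = log L_i(beta_hat(eps) | eps)`` — with the mean
parameters re-maximized by IRLS at every eps — against the normal density
of eps.  Each gene's integral is evaluated by Laplace's method at the
mode ``eps_i*`` of ``g_i(eps) = l_i(eps) - eps^2 / (2 sigma^2)``::

    log term_i = g_i(eps_i*) - 0.5 * log(sigma^2 * (-l_i''(eps_i*) + 1/sigma^2))

and sigma is estimated by maximizing the summed log terms over a bracketed
1-D search.  Because ``l_i`` does not depend on sigma, it is tabulated once
per gene on a shared eps grid and interpolated with a cubic spline; the
per-sigma work is then a cheap per-gene Newton search for the mode.

A calibration procedure maps the real-data estimate to the generative
sigma that would reproduce it: simulate at a grid of sigma values, fit a
quadratic to the median estimates, and invert at the observed value, with
a 95% interval from the OLS prediction band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import t as t_dist

from .nbcore import (CountMatrix, design_two_group, fit_nb_glm_matrix,
                     make_offsets)
from .dispersion import (DispersionTrend, apl_values, estimate_pi,
                         evaluate_trend, fit_trend)

EPS_BOUNDS = (-10.0, 10.0)
_FD_STEP = 1e-3  # central-difference step for l_i'' in the generic path


# ---------------------------------------------------------------------------
# Conditional (profile-in-beta) log-likelihood at a dispersion offset
# ---------------------------------------------------------------------------

def conditional_loglik_at_eps(eps, y, X, offsets, theta0):
    """``l_i(eps)``: NB profile log-likelihood at ``phi = exp(theta0 + eps)``.

    ``theta0`` is the per-sample prior mean log dispersion from the trend
    (a scalar is broadcast).  The mean parameters are re-maximized by IRLS.
    Returns ``-inf`` if the inner fit fails to produce a finite likelihood.
    """
    y = np.asarray(y, dtype=float)
    theta0 = np.broadcast_to(np.asarray(theta0, dtype=float), y.shape)
    phi = np.exp(np.clip(theta0 + eps, -40.0, 25.0))
    res = fit_nb_glm_matrix(y[None, :], X, offsets, phi[None, :])
    ll = float(res["loglik"][0])
    if not np.isfinite(ll):
        return -np.inf
    return ll


# ---------------------------------------------------------------------------
# Laplace approximation for a single gene (generic callable contract)
# ---------------------------------------------------------------------------

def laplace_gene_term(sigma, l, eps_bounds=EPS_BOUNDS, return_mode=False):
    """Log Laplace approximation of one gene's integrated likelihood.

    Approximates ``log[(2 pi sigma^2)^(-1/2) * Int exp(l(e) - e^2/(2 s^2)) de]``
    by locating the mode ``e*`` of ``g(e) = l(e) - e^2/(2 sigma^2)`` (Newton
    from 0, golden-section fallback) and applying the Gaussian curvature
    correction.  Exact whenever ``l`` is quadratic.  Falls back to
    trapezoidal quadrature with a warning if the curvature at the candidate
    mode is not negative.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s2 = sigma * sigma
    h = _FD_STEP

    def d1(e):
        return (l(e + h) - l(e - h)) / (2 * h)

    def d2(e):
        return (l(e + h) - 2 * l(e) + l(e - h)) / (h * h)

    e = 0.0
    ok = False
    for _ in range(100):
        gp = d1(e) - e / s2
        gpp = d2(e) - 1.0 / s2
        if not np.isfinite(gp) or not np.isfinite(gpp) or gpp >= 0:
            break
        step = gp / gpp
        e_new = float(np.clip(e - step, *eps_bounds))
        if abs(e_new - e) < 1e-12 or abs(gp) < 1e-10:
            e = e_new
            ok = True
            break
        e = e_new
    if not ok:
        res = minimize_scalar(lambda x: -(l(x) - x * x / (2 * s2)),
                              bounds=eps_bounds, method="bounded",
                              options={"xatol": 1e-10})
        e = float(res.x)
        if min(e - eps_bounds[0], eps_bounds[1] - e) < 1e-6:
            warnings.warn("eps mode at the search boundary")

    lpp = d2(e)
    curv = -lpp + 1.0 / s2
    if curv <= 0:
        warnings.warn("non-concave integrand at the candidate mode; "
                      "falling back to quadrature")
        grid = np.linspace(*eps_bounds, 2001)
        g = np.array([l(x) for x in grid]) - grid ** 2 / (2 * s2)
        gmax = g.max()
        term = gmax + np.log(np.trapezoid(np.exp(g - gmax), grid)) \
            - 0.5 * np.log(2 * np.pi * s2)
    else:
        term = (l(e) - e * e / (2 * s2)) - 0.5 * np.log(s2 * curv)
    if return_mode:
        return float(term), float(e)
    return float(term)


# ---------------------------------------------------------------------------
# Vectorised profiler: tabulate l_i(eps) once, reuse for every sigma
# ---------------------------------------------------------------------------

def _eval_per_gene(pp, x):
    """Evaluate a vector-valued PPoly at one abscissa per gene."""
    idx = np.clip(np.searchsorted(pp.x, x) - 1, 0, pp.x.size - 2)
    t = x - pp.x[idx]
    c = pp.c[:, idx, np.arange(x.size)]
    out = c[0]
    for row in c[1:]:
        out = out * t + row
    return out


class SigmaProfiler:
    """Laplace profile log-likelihood of sigma for a fitted trend.

    Tabulates every retained gene's conditional profile log-likelihood on
    a shared eps grid (one vectorised IRLS pass per grid point) and builds
    per-gene cubic splines; ``profile_loglik`` then needs only a Newton
    search for the per-gene modes at each sigma.
    Genes with all-zero counts or an unusable trend value are dropped.
    """

    def __init__(self, cm: CountMatrix, trend: DispersionTrend, design=None,
                 offsets=None, eps_grid=None, adjust=True):
        self.adjust = adjust
        if design is None:
            design = design_two_group(cm.group)
        if offsets is None:
            offsets = make_offsets(cm)
        if eps_grid is None:
            eps_grid = np.arange(EPS_BOUNDS[0], EPS_BOUNDS[1] + 1e-9, 0.25)
        pi = trend.pi_gene
        if pi is None or len(pi) != cm.n_genes:
            pi, _ = estimate_pi(cm, design, offsets)
        usable = (np.isfinite(pi) & (pi > 0)
                  & ~(cm.counts <= 0).all(axis=1))
        self.n_dropped = int((~usable).sum())
        counts = cm.counts[usable].astype(float)
        self.theta0 = np.log(evaluate_trend(trend, pi[usable]))
        self.m = counts.shape[0]
        self.eps_grid = eps_grid
        lmat = np.empty((len(eps_grid), self.m))
        for k, e in enumerate(eps_grid):
            phi = np.exp(np.clip(self.theta0 + e, -40.0, 25.0))
            if adjust:
                # Cox-Reid adjusted conditional likelihood: the adjustment
                # is the Laplace approximation to integrating the mean
                # parameters out, mirroring the Laplace treatment of eps;
                # the unadjusted profile inflates small sigma estimates.
                lmat[k] = apl_values(counts, design, offsets, phi)
            else:
                res = fit_nb_glm_matrix(counts, design, offsets,
                                        phi[:, None])
                lmat[k] = res["loglik"]
        bad = ~np.isfinite(lmat).all(axis=0)
        if bad.any():
            warnings.warn(f"dropping {bad.sum()} genes with non-finite "
                          "conditional likelihoods")
            lmat = lmat[:, ~bad]
            self.theta0 = self.theta0[~bad]
            self.m = lmat.shape[1]
            self.n_dropped += int(bad.sum())
        self._lmat = lmat
        self._spline = CubicSpline(eps_grid, lmat, axis=0)
        self._d1 = self._spline.derivative(1)
        self._d2 = self._spline.derivative(2)
        self._warm = None
        # constant recentring of the prior mean log dispersions: the trend
        # intercept and the mean of eps are confounded, so a shift delta
        # moves the evaluation point (l(theta0 + delta + eps) is the
        # tabulated l at eps + delta) without rebuilding the tables
        self.shift = 0.0

    def _l(self, pp, e):
        x = np.clip(e + self.shift, self.eps_grid[0], self.eps_grid[-1])
        return _eval_per_gene(pp, x)

    def eps_modes(self, sigma):
        """Per-gene modes of ``g_i(eps)`` at the given sigma."""
        s2 = sigma * sigma
        eg = self.eps_grid - self.shift
        if self._warm is None:
            g = self._lmat - eg[:, None] ** 2 / (2 * s2)
            e = eg[np.argmax(g, axis=0)]
        else:
            e = self._warm.copy()
        lo, hi = eg[0], eg[-1]
        for _ in range(60):
            gp = self._l(self._d1, e) - e / s2
            gpp = self._l(self._d2, e) - 1.0 / s2
            step = np.where(gpp < 0, gp / gpp, -np.sign(gp) * 0.1)
            e_new = np.clip(e - step, lo, hi)
            if np.max(np.abs(e_new - e)) < 1e-9:
                e = e_new
                break
            e = e_new
        self._warm = e
        return e

    def recenter(self, sigma, max_iter=10, tol=1e-3):
        """Shift the prior means so the eps modes average to zero.

        The trend intercept and the mean of the dispersion residuals are
        not separately identifiable; this enforces the model's mean-zero
        convention against a trend whose fitted level may be offset.
        Returns the cumulative shift applied.
        """
        for _ in range(max_iter):
            delta = float(np.mean(self.eps_modes(sigma)))
            if abs(delta) < tol:
                break
            self.shift += delta
            self._warm = None
        return self.shift

    def profile_loglik(self, sigma):
        """Summed log Laplace terms over retained genes."""
        s2 = sigma * sigma
        e = self.eps_modes(sigma)
        lval = self._l(self._spline, e)
        lpp = self._l(self._d2, e)
        curv = -lpp + 1.0 / s2
        term = (lval - e ** 2 / (2 * s2)) - 0.5 * np.log(np.maximum(curv, 1e-300) * s2)
        flat = curv <= 0
        if flat.any():
            # quadrature fallback on the tabulated grid for non-concave genes
            eg = self.eps_grid - self.shift
            g = self._lmat[:, flat] - eg[:, None] ** 2 / (2 * s2)
            gmax = g.max(axis=0)
            term[flat] = gmax + np.log(
                np.trapezoid(np.exp(g - gmax), eg, axis=0)) \
                - 0.5 * np.log(2 * np.pi * s2)
        return float(np.sum(term))


def profile_loglik_sigma(sigma, cm, trend, design=None, offsets=None,
                         adjust=True):
    """Laplace profile log-likelihood of sigma (one-shot convenience)."""
    return SigmaProfiler(cm, trend, design, offsets,
                         adjust=adjust).profile_loglik(sigma)


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation of sigma
# ---------------------------------------------------------------------------

@dataclass
class SigmaEstimate:
    """MLE of the residual log-dispersion SD with its profile machinery."""
    sigma_hat: float
    se: float
    profile: np.ndarray = field(repr=False)       # columns (sigma, loglik)
    eps_modes: np.ndarray = field(repr=False)
    theta0: np.ndarray = field(repr=False)
    n_genes_used: int = 0
    n_dropped: int = 0
    at_boundary: bool = False


def estimate_sigma(cm: CountMatrix, trend: DispersionTrend, design=None,
                   offsets=None, sigma_bounds=(1e-3, 5.0), subsample=None,
                   seed=None, recenter=False, adjust=True) -> SigmaEstimate:
    """Estimate sigma by maximizing the Laplace profile likelihood.

    Bracketed Brent search on the log scale over ``sigma_bounds``; the
    standard error comes from the numerical observed information of the
    profile log-likelihood at the maximum.  A maximum at the lower bound
    is reported as ``sigma_hat = 0`` with an undefined standard error.
    ``subsample`` optionally restricts the fit to a random gene subset.

    By default the trend predictions enter as-is (treated as known).
    ``recenter=True`` additionally shifts the prior mean log dispersions
    so the per-gene eps modes average to zero — a fitted trend's level is
    confounded with the residual mean, and an offset level inflates the
    variance estimate; the calibration step absorbs the same effect, so
    recentring is off by default and offered as an option.
    """
    if subsample is not None and subsample < cm.n_genes:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(cm.n_genes, size=subsample, replace=False))
        cm = cm.subset_genes(idx)
        if trend.pi_gene is not None and len(trend.pi_gene) != cm.n_genes:
            trend = DispersionTrend(kind=trend.kind, alpha=trend.alpha,
                                    center=trend.center,
                                    smooth_x=trend.smooth_x,
                                    smooth_y=trend.smooth_y)
    prof = SigmaProfiler(cm, trend, design, offsets, adjust=adjust)
    lo, hi = sigma_bounds

    def maximize():
        res = minimize_scalar(lambda ls: -prof.profile_loglik(np.exp(ls)),
                              bounds=(np.log(lo), np.log(hi)),
                              method="bounded", options={"xatol": 1e-4})
        return float(np.exp(res.x))

    sigma_hat = maximize()
    if recenter:
        for _ in range(4):
            old_shift = prof.shift
            prof.recenter(sigma_hat)
            if abs(prof.shift - old_shift) < 1e-3:
                break
            prof._warm = None
            sigma_hat = maximize()
    at_boundary = sigma_hat <= lo * 1.1
    grid = np.unique(np.concatenate([
        np.geomspace(max(lo, sigma_hat / 4), min(hi, sigma_hat * 2.5), 11),
        [sigma_hat]]))
    profile = np.column_stack([grid, [prof.profile_loglik(s) for s in grid]])
    if at_boundary:
        return SigmaEstimate(0.0, float("nan"), profile,
                             prof.eps_modes(sigma_hat), prof.theta0,
                             prof.m, prof.n_dropped, True)
    h = max(1e-3, 5e-3 * sigma_hat)
    f0 = prof.profile_loglik(sigma_hat)
    d2 = (prof.profile_loglik(sigma_hat + h) - 2 * f0
          + prof.profile_loglik(max(sigma_hat - h, lo / 2))) / h ** 2
    se = 1.0 / np.sqrt(-d2) if d2 < 0 else float("nan")
    return SigmaEstimate(sigma_hat, float(se), profile,
                         prof.eps_modes(sigma_hat), prof.theta0,
                         prof.m, prof.n_dropped, False)


# ---------------------------------------------------------------------------
# Calibration of sigma via simulation
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """A quadratic calibration curve inverted at the observed estimate."""
    grid: np.ndarray
    sigma_hats: np.ndarray          # (levels, reps)
    medians: np.ndarray
    quad_coeffs: np.ndarray         # ascending powers (c0, c1, c2)
    sigma_tilde: float
    ci95: tuple
    extrapolated: bool = False


def quadratic_calibration(grid, sigma_hats, sigma_hat_real) -> CalibrationResult:
    """Fit the quadratic calibration curve and invert it.

    ``sigma_hats`` is (levels, reps) — or (levels,) of medians.  The
    calibrated value solves ``quad(sigma) = sigma_hat_real``; the 95%
    interval comes from the intersections of the OLS prediction band with
    the same horizontal line.
    """
    grid = np.asarray(grid, dtype=float)
    sh = np.atleast_2d(np.asarray(sigma_hats, dtype=float))
    if sh.shape[0] == 1 and len(grid) > 1:
        sh = sh.T
    medians = np.median(sh, axis=1)
    K = len(grid)
    if K < 3:
        raise ValueError("need at least three grid levels for a quadratic")
    Xd = np.vander(grid, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(Xd, medians, rcond=None)
    # The observed sigma_hat is a single realization of the estimator, so
    # the band is a single-observation prediction interval; the residual
    # scale pools all replicate deviations around the fitted curve for a
    # stable estimate even on short grids.
    if sh.shape[1] > 1:
        resid = sh - (Xd @ coef)[:, None]
        dof = sh.size - 3
    else:
        resid = medians - Xd @ coef
        dof = K - 3
    s = np.sqrt(np.sum(resid ** 2) / dof) if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(Xd.T @ Xd)

    def curve(x):
        return coef[0] + coef[1] * x + coef[2] * x * x

    def band_half_width(x):
        if s == 0.0:
            return 0.0
        x0 = np.array([1.0, x, x * x])
        return t_dist.ppf(0.975, dof) * s * np.sqrt(1.0 + x0 @ XtX_inv @ x0)

    lo, hi = grid.min(), grid.max()
    span = hi - lo
    ext_lo, ext_hi = lo - 0.75 * span, hi + 0.75 * span
    roots = np.roots([coef[2], coef[1], coef[0] - sigma_hat_real])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    inside = real[(real >= lo) & (real <= hi)]
    extrapolated = False
    if inside.size == 1:
        sigma_tilde = float(inside[0])
    elif inside.size > 1:
        warnings.warn("both quadratic roots inside the grid hull; choosing "
                      "the one on the increasing branch")
        slopes = coef[1] + 2 * coef[2] * inside
        cand = inside[slopes > 0]
        sigma_tilde = float(cand[0] if cand.size else inside[0])
    else:
        extrapolated = True
        warnings.warn("no root inside the calibration grid; extrapolating")
        if real.size:
            sigma_tilde = float(real[np.argmin(np.minimum(
                np.abs(real - lo), np.abs(real - hi)))])
        else:
            sigma_tilde = float(grid[np.argmin(np.abs(medians - sigma_hat_real))])

    def _crossing(sign):
        # sign=+1: upper band (gives the lower CI end for an increasing curve)
        def f(x):
            return curve(x) + sign * band_half_width(x) - sigma_hat_real
        xs = np.linspace(ext_lo, ext_hi, 400)
        fv = np.array([f(x) for x in xs])
        # pick the sign change nearest to sigma_tilde
        idx = np.where(np.diff(np.sign(fv)) != 0)[0]
        if idx.size == 0:
            return ext_lo if sign > 0 else ext_hi
        best = idx[np.argmin(np.abs(xs[idx] - sigma_tilde))]
        return brentq(f, xs[best], xs[best + 1])

    if s == 0.0:
        ci = (sigma_tilde, sigma_tilde)
    else:
        ci = tuple(sorted((_crossing(+1), _crossing(-1))))
    return CalibrationResult(grid=grid, sigma_hats=sh, medians=medians,
                             quad_coeffs=coef, sigma_tilde=sigma_tilde,
                             ci95=ci, extrapolated=extrapolated)


DEFAULT_ACCURACY_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9, 1.2, 1.5, 2.0)


def accuracy_simulation(sigma_levels=DEFAULT_ACCURACY_LEVELS, reps=3,
                        m=5000, n=7, trend_alpha=None, trend_kind="nbq",
                        seed=0):
    """Accuracy study of the sigma estimator on single-group data.

    For each sigma level, simulates ``reps`` datasets of ``m`` genes and
    ``n`` replicates with log-normal baseline means and a known dispersion
    trend (log-quadratic by default, or a constant for
    ``trend_kind='common'``), then re-estimates sigma with that trend
    supplied.  Returns ``(levels, estimates, medians)`` where
    ``estimates`` is (levels, reps).
    """
    from .simulate import DEFAULT_TREND_ALPHA, simulate_single_group

    if trend_alpha is None:
        trend_alpha = (DEFAULT_TREND_ALPHA if trend_kind == "nbq"
                       else DEFAULT_TREND_ALPHA[:1])
    levels = np.asarray(sigma_levels, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(levels) * reps)
    est = np.empty((len(levels), reps))
    for k, sig in enumerate(levels):
        for r in range(reps):
            child = children[k * reps + r]
            sim_seed = int(child.generate_state(1)[0] % (2 ** 31))
            if trend_kind == "common":
                trend = DispersionTrend(kind="common",
                                        alpha=np.asarray(trend_alpha))
            else:
                trend = None
            cm, truth = simulate_single_group(
                m=m, n=n, sigma=float(sig), seed=sim_seed, trend=trend,
                trend_alpha=tuple(trend_alpha))
            est[k, r] = estimate_sigma(cm, truth.trend).sigma_hat
    return levels, est, np.median(est, axis=1)


DEFAULT_CALIBRATION_GRID = (0.5, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.5)


def calibrate_sigma(simulate_fn, sigma_hat_real, grid=DEFAULT_CALIBRATION_GRID,
                    reps=3, seed=0, trend_kind="nbq") -> CalibrationResult:
    """Simulation-based calibration of the sigma estimate.

    ``simulate_fn(sigma, seed) -> CountMatrix`` must generate a dataset
    whose dispersions use the *true* relative frequencies as the trend
    predictor.  Each simulated dataset is refitted from scratch (trend on
    estimated frequencies, then the sigma MLE), mirroring the analysis of
    the real data.  Default grid: eight levels from 0.5 to 1.5, three
    replicates each.
    """
    if reps < 3:
        raise ValueError("need at least three replicates per grid level")
    grid = np.asarray(grid, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid) * reps)
    sigma_hats = np.empty((len(grid), reps))
    for k, sig in enumerate(grid):
        for r in range(reps):
            child = children[k * reps + r]
            sim_seed = int(child.generate_state(1)[0] % (2 ** 31))
            cm = simulate_fn(float(sig), sim_seed)
            trend = fit_trend(cm, trend_kind)
            sigma_hats[k, r] = estimate_sigma(cm, trend).sigma_hat
    return quadratic_calibration(grid, sigma_hats, sigma_hat_real)
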