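"""Genewise NB dispersion estimation and dispersion-trend models.

The trend models relate log dispersion to the relative mean frequency
``pi = mu / (N * R)`` of a gene::

    log(phi) = f(log pi; alpha)

with ``f`` constant (common), linear (NBP), quadratic (NBQ) or a
non-parametric smooth.  Parametric trends are fitted by maximizing the sum
over genes of Cox-Reid adjusted profile likelihoods (APL); the smooth
trend is a locally weighted regression of genewise log-dispersion
estimates on log relative abundance.  Empirical-Bayes tagwise shrinkage
maximizes a weighted sum of the genewise APL and a neighborhood-averaged
prior APL anchored at the fitted trend.

Log relative frequencies are centred at their mean before entering the
parametric trends; the centring constant is stored on the fitted trend so
that evaluation is independent of the parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .nbcore import (CountMatrix, fit_nb_glm_matrix, nb_loglik_terms,
                     make_offsets, design_two_group)

#: search range for genewise dispersion optimization, on the log scale
LOG_PHI_MIN, LOG_PHI_MAX = -18.0, np.log(1e3)

#: genewise dispersions are floored here before entering the smooth trend
PHI_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Method-of-moments estimator
# ---------------------------------------------------------------------------

def mom_dispersion(y):
    """Method-of-moments dispersion ``sum[(y - m)^2 - m] / (n m^2)``.

    ``m`` is the sample mean.  May be negative (underdispersed data);
    returns NaN when the mean is zero.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    mean = y.mean()
    if mean <= 0:
        return float("nan")
    return float(np.sum((y - mean) ** 2 - mean) / (y.size * mean ** 2))


def mom_dispersion_matrix(counts):
    """Row-wise method-of-moments dispersions of a count matrix."""
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.sum((counts - mean[:, None]) ** 2 - mean[:, None], axis=1) \
            / (counts.shape[1] * mean ** 2)
    return np.where(mean > 0, val, np.nan)


# ---------------------------------------------------------------------------
# Profile likelihood and Cox-Reid adjustment
# ---------------------------------------------------------------------------

def _profile_fit(counts, X, offsets, phi_gene, beta0=None):
    """Vectorised IRLS fit with one dispersion per gene."""
    phi = np.asarray(phi_gene, dtype=float)[:, None]
    return fit_nb_glm_matrix(counts, X, offsets, phi, beta0=beta0)


def profile_loglik(counts, X, offsets, phi_gene, beta0=None):
    """Per-gene profile log-likelihood ``max_beta l(beta, phi)``."""
    return _profile_fit(counts, X, offsets, phi_gene, beta0=beta0)["loglik"]


def apl_values(counts, X, offsets, phi_gene, beta0=None):
    """Per-gene Cox-Reid adjusted profile log-likelihood.

    ``APL_i = l_i(beta_hat(phi), phi) - 0.5 * log det(X' W X)`` with ``W``
    the IRLS weight matrix at the fitted mean.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(X, dtype=float)
    phi = np.asarray(phi_gene, dtype=float)
    if phi.ndim == 0:
        phi = np.full(counts.shape[0], float(phi))
    fit = _profile_fit(counts, X, offsets, phi, beta0=beta0)
    w = fit["mu"] / (1.0 + phi[:, None] * fit["mu"])
    A = np.einsum("mn,nk,nl->mkl", w, X, X)
    sign, logdet = np.linalg.slogdet(A + 1e-300 * np.eye(X.shape[1]))
    logdet = np.where(sign > 0, logdet, np.inf)
    return fit["loglik"] - 0.5 * logdet


def adjusted_profile_loglik(phi, y, X, offsets):
    """Cox-Reid APL of a single gene at dispersion ``phi``."""
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    y = np.asarray(y, dtype=float)
    return float(apl_values(y[None, :], X, offsets, np.array([phi]))[0])


# ---------------------------------------------------------------------------
# Genewise maximum-likelihood dispersion
# ---------------------------------------------------------------------------

def genewise_phi_mle(y, X, offsets, use_apl=False):
    """Profile-likelihood dispersion MLE for one gene.

    One-dimensional bounded optimization over ``log(phi)`` with nested
    IRLS.  Underdispersed data yield the boundary value 0.
    """
    y = np.asarray(y, dtype=float)[None, :]

    def negobj(logphi):
        phi = np.array([np.exp(logphi)])
        if use_apl:
            return -float(apl_values(y, X, offsets, phi)[0])
        return -float(profile_loglik(y, X, offsets, phi)[0])

    res = minimize_scalar(negobj, bounds=(LOG_PHI_MIN, LOG_PHI_MAX),
                          method="bounded", options={"xatol": 1e-6})
    # boundary check: effectively-Poisson likelihood at phi -> 0
    if -res.fun <= -negobj(LOG_PHI_MIN) + 1e-10 or res.x <= LOG_PHI_MIN + 1e-4:
        return 0.0
    return float(np.exp(res.x))


def _parabolic_refine(grid, values):
    """Continuous argmax of per-gene grids via 3-point parabola.

    ``values`` is (m, G); returns (m,) refined abscissae and the refined
    maxima.  Boundary maxima stay on the grid.
    """
    m, G = values.shape
    k = np.argmax(values, axis=1)
    kc = np.clip(k, 1, G - 2)
    y0, y1, y2 = (values[np.arange(m), kc - 1], values[np.arange(m), kc],
                  values[np.arange(m), kc + 1])
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        dx = 0.5 * (y0 - y2) / denom
    dx = np.where((denom < -1e-12) & (k == kc), np.clip(dx, -0.5, 0.5), 0.0)
    step = grid[1] - grid[0]
    x = grid[kc] + dx * step
    x = np.where(k == kc, x, grid[k])
    fmax = y1 - 0.25 * (y0 - y2) * dx
    fmax = np.where(k == kc, fmax, values[np.arange(m), k])
    return x, fmax


def genewise_phi_mle_matrix(counts, X, offsets, use_apl=False,
                            grid=None):
    """Vectorised genewise dispersion MLEs via a log-phi grid.

    Evaluates the (adjusted) profile likelihood of every gene on a shared
    ``log(phi)`` grid and refines the per-gene maximum with a parabolic
    step.  Genes maximized at the lower boundary are returned as 0.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    m = counts.shape[0]
    if grid is None:
        grid = np.arange(-12.0, LOG_PHI_MAX + 1e-9, 0.2)
    vals = np.empty((m, len(grid)))
    for g, lp in enumerate(grid):
        phi = np.full(m, np.exp(lp))
        if use_apl:
            vals[:, g] = apl_values(counts, X, offsets, phi)
        else:
            vals[:, g] = profile_loglik(counts, X, offsets, phi)
    logphi, _ = _parabolic_refine(grid, vals)
    phi_hat = np.exp(logphi)
    phi_hat[np.argmax(vals, axis=1) == 0] = 0.0
    return phi_hat


# ---------------------------------------------------------------------------
# Dispersion trends
# ---------------------------------------------------------------------------

@dataclass
class DispersionTrend:
    """A fitted trend ``log(phi) = f(log pi; alpha)``.

    ``kind`` is one of ``common``, ``nbp``, ``nbq``, ``smooth``.  For the
    parametric kinds ``alpha`` holds (alpha0[, alpha1[, alpha2]]) acting on
    the centred predictor ``z = log(pi) - center``.  The smooth kind keeps
    an interpolation table (flat extrapolation beyond the fitted range).
    """
    kind: str
    alpha: np.ndarray = None
    center: float = 0.0
    smooth_x: np.ndarray = field(default=None, repr=False)
    smooth_y: np.ndarray = field(default=None, repr=False)
    pi_gene: np.ndarray = field(default=None, repr=False)
    phi_gene: np.ndarray = field(default=None, repr=False)

    def log_phi(self, pi):
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("relative mean frequencies must be positive")
        logpi = np.log(pi)
        if self.kind == "smooth":
            return np.interp(logpi, self.smooth_x, self.smooth_y)
        z = logpi - self.center
        a = np.asarray(self.alpha, dtype=float)
        out = np.full(logpi.shape, a[0], dtype=float)
        if self.kind in ("nbp", "nbq"):
            out = out + a[1] * z
        if self.kind == "nbq":
            out = out + a[2] * z ** 2
        return out


def evaluate_trend(trend: DispersionTrend, pi):
    """Dispersions ``phi = exp(f(pi))`` at relative mean frequencies."""
    return np.exp(np.clip(trend.log_phi(pi), -40.0, 20.0))


def estimate_pi(cm: CountMatrix, design=None, offsets=None):
    """Preliminary per-gene relative mean frequencies.

    Fits the mean model in the Poisson limit and returns the geometric
    mean over samples of ``mu_hat / (N R)``; zero-mean genes get NaN.
    """
    if design is None:
        design = design_two_group(cm.group)
    if offsets is None:
        offsets = make_offsets(cm)
    fit = fit_nb_glm_matrix(cm.counts, design, offsets, 0.0)
    with np.errstate(divide="ignore"):
        logpi = np.log(fit["mu"]) - offsets
    pi = np.exp(logpi.mean(axis=1))
    pi[(cm.counts <= 0).all(axis=1)] = np.nan
    return pi, fit["mu"]


def _trend_objective_builder(counts, X, offsets, pi):
    """Returns f(logphi_gene) -> total APL, with cached warm starts."""
    counts = np.asarray(counts, dtype=float)
    state = {"beta0": None}

    def total_apl(logphi_gene):
        phi = np.exp(np.clip(logphi_gene, -30.0, 15.0))
        vals = apl_values(counts, X, offsets, phi, beta0=state["beta0"])
        return float(np.sum(vals))

    return total_apl


def fit_trend(cm: CountMatrix, kind: str, design=None, offsets=None,
              pi=None, lowess_frac=0.4) -> DispersionTrend:
    """Fit a dispersion trend of the requested kind.

    Parametric kinds (``common``, ``nbp``, ``nbq``) maximize the summed
    Cox-Reid APL over the trend parameters.  The ``smooth`` kind runs a
    lowess regression of genewise APL-maximizing log dispersions on log
    relative abundance.  Genes with all-zero counts are excluded from the
    fit (the returned trend still evaluates anywhere).
    """
    kind = kind.lower()
    if kind not in ("common", "nbp", "nbq", "smooth"):
        raise ValueError(f"unknown trend kind: {kind}")
    if design is None:
        design = design_two_group(cm.group)
    if offsets is None:
        offsets = make_offsets(cm)
    if pi is None:
        pi, _ = estimate_pi(cm, design, offsets)
    keep = np.isfinite(pi) & (pi > 0) & ~(cm.counts <= 0).all(axis=1)
    counts = cm.counts[keep].astype(float)
    logpi = np.log(pi[keep])
    n_par = {"common": 1, "nbp": 2, "nbq": 3}.get(kind, 0)
    if kind != "smooth" and keep.sum() < n_par + 1:
        raise ValueError("fewer usable genes than trend parameters")

    if kind == "smooth":
        # local shared-likelihood estimate: genes are binned by abundance
        # and the summed APL of each bin is maximized over a common log
        # dispersion; the bin maximizers are interpolated linearly with
        # flat extrapolation.  Pooling ~100 genes per bin removes the
        # small-sample bias of individual genewise estimates.
        m = counts.shape[0]
        grid = np.arange(-12.0, LOG_PHI_MAX + 1e-9, 0.2)
        apl = np.empty((m, len(grid)))
        for g, lp in enumerate(grid):
            apl[:, g] = apl_values(counts, design, offsets,
                                   np.full(m, np.exp(lp)))
        nbins = int(np.clip(m // 100, 4, 25))
        order = np.argsort(logpi, kind="stable")
        bins = np.array_split(order, nbins)
        centers = np.array([logpi[b].mean() for b in bins])
        bin_vals = np.vstack([apl[b].sum(axis=0) for b in bins])
        logphi_bin, _ = _parabolic_refine(grid, bin_vals)
        srt = np.argsort(centers)
        phi_gene = np.full(cm.n_genes, np.nan)
        phi_gene[keep] = np.exp(np.interp(logpi, centers[srt],
                                          logphi_bin[srt]))
        return DispersionTrend(kind="smooth", smooth_x=centers[srt],
                               smooth_y=logphi_bin[srt],
                               pi_gene=pi, phi_gene=phi_gene)

    center = float(logpi.mean())
    z = logpi - center
    total_apl = _trend_objective_builder(counts, design, offsets, pi)

    # common trend: 1-D bounded search, also the starting point for others
    res0 = minimize_scalar(lambda a0: -total_apl(np.full(len(z), a0)),
                           bounds=(-15.0, 7.0), method="bounded",
                           options={"xatol": 1e-6})
    a0 = float(res0.x)
    if kind == "common":
        return DispersionTrend(kind="common", alpha=np.array([a0]),
                               center=center, pi_gene=pi)

    def neg(alpha):
        f = alpha[0] + alpha[1] * z
        if kind == "nbq":
            f = f + alpha[2] * z ** 2
        return -total_apl(f)

    x0 = np.array([a0, 0.0, 0.0][: n_par])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
    if not res.success:
        warnings.warn(f"trend optimization did not fully converge: {res.message}")
    return DispersionTrend(kind=kind, alpha=np.asarray(res.x), center=center,
                           pi_gene=pi)


# ---------------------------------------------------------------------------
# Gamma log-linear diagnostic regression
# ---------------------------------------------------------------------------

def gamma_loglinear_fit(phi_mom, pi, degree: int = 2):
    """Polynomial gamma log-linear regression of MOM dispersions on log(pi).

    Only genes with a positive method-of-moments dispersion enter the fit.
    Returns ``(coefficients, proportion_explained)`` where the proportion
    is ``1 - SSE/SST`` computed on ``log(phi_mom)`` against the fitted log
    means.
    """
    import statsmodels.api as smapi
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    phi_mom = np.asarray(phi_mom, dtype=float)
    pi = np.asarray(pi, dtype=float)
    use = np.isfinite(phi_mom) & (phi_mom > 0) & np.isfinite(pi) & (pi > 0)
    if use.sum() < degree + 2:
        raise ValueError("too few genes with positive MOM dispersion")
    x = np.log(pi[use])
    Xd = np.column_stack([x ** k for k in range(degree + 1)])
    model = smapi.GLM(phi_mom[use], Xd,
                      family=smapi.families.Gamma(link=smapi.families.links.Log()))
    fit = model.fit()
    eta = Xd @ fit.params
    logphi = np.log(phi_mom[use])
    sse = np.sum((logphi - eta) ** 2)
    sst = np.sum((logphi - logphi.mean()) ** 2)
    prop = 1.0 - sse / sst if sst > 0 else np.nan
    return np.asarray(fit.params), float(prop)


# ---------------------------------------------------------------------------
# Empirical-Bayes tagwise shrinkage
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageConfig:
    """Prior weight and neighborhood for tagwise dispersion shrinkage."""
    g0: float = 10.0
    window: int = 50

    def __post_init__(self):
        if self.g0 < 0:
            raise ValueError("prior weight G0 must be non-negative")


def _window_mean_sorted(values, order, window):
    """Sliding-window mean over rows of ``values`` taken in sorted order."""
    m, G = values.shape
    w = max(1, min(window, m))
    sorted_vals = values[order]
    csum = np.vstack([np.zeros((1, G)), np.cumsum(sorted_vals, axis=0)])
    pos = np.arange(m)
    lo = np.clip(pos - w // 2, 0, m - w)
    hi = lo + w
    means_sorted = (csum[hi] - csum[lo]) / w
    out = np.empty_like(means_sorted)
    out[order] = means_sorted
    return out


def tagwise_shrink(cm: CountMatrix, trend: DispersionTrend,
                   cfg: ShrinkageConfig = None, design=None, offsets=None,
                   grid_step: float = 0.1):
    """Empirical-Bayes tagwise dispersions.

    Per gene, maximizes ``APL_i(phi) + G0 * APL_S(phi)`` on a shared
    log-phi grid (with parabolic refinement), where the prior ``APL_S`` is
    the average APL of the ``window`` genes nearest in average log-cpm,
    re-anchored in log-phi so that its maximizer sits at the gene's trend
    value.  ``G0 = 0`` recovers the genewise APL maximizer; large ``G0``
    recovers the trend.
    """
    cfg = cfg or ShrinkageConfig()
    if design is None:
        design = design_two_group(cm.group)
    if offsets is None:
        offsets = make_offsets(cm)
    counts = cm.counts.astype(float)
    m = counts.shape[0]
    grid = np.arange(-12.0, 5.0 + 1e-9, grid_step)
    G = len(grid)
    apl = np.empty((m, G))
    for g, lp in enumerate(grid):
        apl[:, g] = apl_values(counts, design, offsets, np.full(m, np.exp(lp)))

    # neighborhood prior in average log-cpm order
    with np.errstate(divide="ignore"):
        alogcpm = np.log2(np.maximum(
            (counts / cm.lib_size * 1e6).mean(axis=1), 1e-9))
    order = np.argsort(alogcpm, kind="stable")
    apl_s = _window_mean_sorted(apl, order, cfg.window)

    # anchor the prior at the trend: shift each gene's APL_S so its
    # maximizer coincides with the trend dispersion
    ls_star, _ = _parabolic_refine(grid, apl_s)
    pi = trend.pi_gene
    if pi is None or len(pi) != m:
        pi, _ = estimate_pi(cm, design, offsets)
    pi_safe = np.where(np.isfinite(pi) & (pi > 0), pi, np.nanmedian(pi))
    lt = np.clip(np.log(evaluate_trend(trend, pi_safe)), grid[0], grid[-1])
    delta = lt - ls_star
    # evaluate APL_S at (grid - delta_i) by linear interpolation
    frac_idx = (grid[None, :] - delta[:, None] - grid[0]) / grid_step
    frac_idx = np.clip(frac_idx, 0, G - 1)
    k0 = np.floor(frac_idx).astype(int)
    k1 = np.minimum(k0 + 1, G - 1)
    fr = frac_idx - k0
    rows = np.arange(m)[:, None]
    apl_s_shift = apl_s[rows, k0] * (1 - fr) + apl_s[rows, k1] * fr

    objective = apl + cfg.g0 * apl_s_shift
    logphi, _ = _parabolic_refine(grid, objective)
    bad = ~np.isfinite(logphi)
    if bad.any():
        warnings.warn(f"{bad.sum()} genes fell back to the trend dispersion")
        logphi[bad] = lt[bad]
    return np.exp(logphi)
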