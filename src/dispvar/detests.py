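"""Six representative two-group differential-expression test strategies.

All methods share the NB log-linear mean model and the null hypothesis of
zero log fold change; they differ only in how the per-gene dispersion is
obtained and in the reference distribution:

================  ==========================================  =========
method            dispersion                                  test
================  ==========================================  =========
``genewise``      per-gene profile-likelihood MLE             LRT
``common``        one constant for all genes                  LRT
``nbq``           log-quadratic parametric trend              LRT
``trended``       non-parametric smooth trend                 LRT
``tagwise``       empirical-Bayes shrinkage toward the trend  LRT
``ql``            trend NB dispersion + quasi-dispersion       QL F
================  ==========================================  =========

The quasi-likelihood route models ``Var(Y) = Phi_i * (mu + omega_i mu^2)``:
per-gene mean residual deviances ``s_i^2 = D_i / d_i`` follow a scaled-F
marginal ``s_i^2 ~ s0^2 F(d_i, d0)`` whose parameters are moment-matched
across genes; the shrunk quasi-dispersion enters an F-test with ``d0``
extra denominator degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.special import polygamma, digamma
from scipy.stats import chi2, f as f_dist

from .nbcore import (CountMatrix, design_two_group, fit_nb_glm_matrix,
                     lrt_from_logliks, make_offsets, nb_deviance)
from .dispersion import (ShrinkageConfig, estimate_pi, evaluate_trend,
                         fit_trend, genewise_phi_mle_matrix, tagwise_shrink)
from .evaluate import bh_adjust

METHODS = ("genewise", "common", "nbq", "trended", "tagwise", "ql")


@dataclass
class DEConfig:
    """Knobs shared by the test strategies."""
    g0: float = 10.0
    window: int = 50
    tagwise_trend: str = "smooth"
    ql_trend: str = "smooth"
    d0_method: str = "moments"
    zero_df_correction: bool = False
    fixed_dispersion: float = None   # overrides all dispersion estimation


@dataclass
class DETestResult:
    """Per-gene results of one DE test method."""
    method: str
    table: pd.DataFrame = field(repr=False)

    @property
    def pvalue(self):
        return self.table["pvalue"].to_numpy()

    @property
    def qvalue(self):
        return self.table["qvalue"].to_numpy()

    @property
    def logfc(self):
        return self.table["logfc"].to_numpy()


@dataclass
class QLFit:
    """Quasi-likelihood dispersion machinery for all genes."""
    omega: np.ndarray
    deviance: np.ndarray
    df_resid: np.ndarray
    s2: np.ndarray
    s0_sq: float = None
    d0: float = None

    @property
    def phi_shrunk(self):
        return _shrink_quasi_dispersion(self.s2, self.df_resid,
                                        self.s0_sq, self.d0)


class DEAnalysis:
    """Shared per-dataset state so several methods reuse one set of fits."""

    def __init__(self, cm: CountMatrix, config: DEConfig = None):
        if len(np.unique(cm.group)) != 2:
            raise ValueError("two sample groups are required")
        if min(np.bincount(cm.group)[1:]) < 2:
            warnings.warn("a group has fewer than two samples; dispersion "
                          "estimates will be unstable")
        self.cm = cm
        self.config = config or DEConfig()
        self.design = design_two_group(cm.group)
        self.null_design = np.ones((cm.n_samples, 1))
        self.offsets = make_offsets(cm)
        self.nonzero = ~(cm.counts <= 0).all(axis=1)
        self.counts_nz = cm.counts[self.nonzero].astype(float)

    @cached_property
    def pi(self):
        pi, _ = estimate_pi(self.cm, self.design, self.offsets)
        return pi

    def _trend(self, kind):
        return fit_trend(self.cm, kind, self.design, self.offsets, pi=self.pi)

    @cached_property
    def trend_smooth(self):
        return self._trend("smooth")

    @cached_property
    def phi_genewise(self):
        # Cox-Reid adjusted profile likelihood: the adjustment compensates
        # for the estimated mean parameters, without which the genewise
        # dispersion is biased low and the LRT markedly anticonservative
        # at typical replicate numbers.
        phi = np.full(self.cm.n_genes, np.nan)
        phi[self.nonzero] = genewise_phi_mle_matrix(
            self.counts_nz, self.design, self.offsets, use_apl=True)
        return phi

    def _trend_phi(self, kind):
        trend = self.trend_smooth if kind == "smooth" else self._trend(kind)
        pi_safe = np.where(np.isfinite(self.pi) & (self.pi > 0), self.pi,
                           np.nanmedian(self.pi))
        return evaluate_trend(trend, pi_safe), trend

    def dispersion_for(self, method):
        cfg = self.config
        if cfg.fixed_dispersion is not None:
            return np.full(self.cm.n_genes, float(cfg.fixed_dispersion))
        if method == "genewise":
            return self.phi_genewise
        if method == "common":
            return self._trend_phi("common")[0]
        if method == "nbq":
            return self._trend_phi("nbq")[0]
        if method == "trended":
            return self._trend_phi("smooth")[0]
        if method == "tagwise":
            trend = (self.trend_smooth if cfg.tagwise_trend == "smooth"
                     else self._trend(cfg.tagwise_trend))
            return tagwise_shrink(self.cm, trend,
                                  ShrinkageConfig(g0=cfg.g0, window=cfg.window),
                                  self.design, self.offsets)
        raise ValueError(f"unknown method: {method}")

    def _fits(self, phi):
        phi_col = np.where(np.isfinite(phi), phi, 0.0)[:, None]
        full = fit_nb_glm_matrix(self.cm.counts.astype(float), self.design,
                                 self.offsets, phi_col)
        null = fit_nb_glm_matrix(self.cm.counts.astype(float),
                                 self.null_design, self.offsets, phi_col)
        return full, null


def de_test(cm: CountMatrix, method: str, config: DEConfig = None,
            analysis: DEAnalysis = None) -> DETestResult:
    """Run one DE test method on a two-group count matrix.

    Returns per-gene p-values, BH-adjusted q-values, estimated log fold
    changes (natural log), test statistics and the dispersion used.
    All-zero genes get ``p = q = 1`` and are excluded from the BH
    denominator.  Pass a shared :class:`DEAnalysis` to reuse fits across
    methods on the same dataset.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    an = analysis if analysis is not None else DEAnalysis(cm, config)

    if method == "ql":
        return _ql_test(an)

    phi = an.dispersion_for(method)
    full, null = an._fits(phi)
    stat, p = lrt_from_logliks(full["loglik"], null["loglik"], df=1)
    return _assemble(an, method, full["beta"][:, 1], stat, p, phi)


def de_test_many(cm: CountMatrix, methods=METHODS, config: DEConfig = None):
    """Run several methods with shared per-dataset fits."""
    an = DEAnalysis(cm, config)
    return {m: de_test(cm, m, analysis=an) for m in methods}


def _assemble(an: DEAnalysis, method, logfc, stat, p, phi):
    p = np.where(an.nonzero, p, 1.0)
    stat = np.where(an.nonzero, stat, 0.0)
    q = np.full(len(p), 1.0)
    valid = an.nonzero & np.isfinite(p)
    q[valid] = bh_adjust(p[valid])
    table = pd.DataFrame({
        "gene_id": an.cm.gene_ids,
        "logfc": logfc,
        "stat": stat,
        "pvalue": p,
        "qvalue": q,
        "dispersion": phi,
        "method": method,
    })
    return DETestResult(method=method, table=table)


# ---------------------------------------------------------------------------
# Quasi-likelihood machinery
# ---------------------------------------------------------------------------

def estimate_ql_dispersions(cm: CountMatrix, trend, design=None,
                            offsets=None, omega=None,
                            zero_df_correction=False) -> QLFit:
    """Residual deviances and raw quasi-dispersions at trend NB dispersions.

    ``omega_i`` comes from the supplied trend unless given explicitly.
    ``s_i^2 = D_i / d_i`` with ``d_i = n - p`` by default; the optional
    zero-count correction reduces ``d_i`` by the fraction of samples whose
    fitted cell is entirely zero (a bias allowance for exact zeros).
    Saturated genes (``d_i <= 0``) are excluded via NaN.
    """
    if design is None:
        design = design_two_group(cm.group)
    if offsets is None:
        offsets = make_offsets(cm)
    counts = cm.counts.astype(float)
    n, p = design.shape
    if omega is None:
        pi = trend.pi_gene
        if pi is None or len(pi) != cm.n_genes:
            pi, _ = estimate_pi(cm, design, offsets)
        pi_safe = np.where(np.isfinite(pi) & (pi > 0), pi, np.nanmedian(pi))
        omega = evaluate_trend(trend, pi_safe)
    omega = np.asarray(omega, dtype=float)
    fit = fit_nb_glm_matrix(counts, design, offsets, omega[:, None])
    dev = nb_deviance(counts, fit["mu"], omega[:, None])
    d = np.full(cm.n_genes, float(n - p))
    if zero_df_correction:
        zero_frac = (counts <= 0).sum(axis=1) / n
        d = np.maximum(d - zero_frac * (n - p), 1e-6)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(d > 0, dev / d, np.nan)
    return QLFit(omega=omega, deviance=dev, df_resid=d, s2=s2)


def estimate_d0_s0(s2, d, method="moments"):
    """Moment-match the scaled-F marginal of mean residual deviances.

    With homogeneous residual df ``d`` the first two moments of
    ``s^2 ~ s0^2 F(d, d0)`` are solved for ``(s0^2, d0)``; zero or
    negative excess variance yields ``d0 = inf``.  ``method="log"``
    matches the mean/variance of ``log s^2`` (digamma/trigamma moments),
    which also accommodates heterogeneous ``d_i``.
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (d > 0)
    if method == "log":
        ok = ok & (s2 > 0)
    s2, d = s2[ok], d[ok]
    if s2.size < 10:
        raise ValueError("need at least 10 genes with usable s^2")

    if method == "log":
        e = np.log(s2)
        excess = e.var(ddof=1) - polygamma(1, d / 2).mean()
        if excess <= 0:
            d0 = np.inf
            log_s0 = e.mean() - (digamma(d / 2) - np.log(d / 2)).mean()
        else:
            from scipy.optimize import brentq
            x = brentq(lambda v: polygamma(1, v) - excess, 1e-6, 1e8)
            d0 = 2.0 * x
            log_s0 = (e.mean() - (digamma(d / 2) - np.log(d / 2)).mean()
                      + digamma(d0 / 2) - np.log(d0 / 2))
        return float(np.exp(log_s0)), float(d0)

    dbar = float(d.mean())
    m1 = float(s2.mean())
    v = float(s2.var(ddof=1))
    if m1 <= 0:
        raise ValueError("mean of s^2 must be positive")
    r = v / m1 ** 2
    if r * dbar <= 2:
        return m1, float("inf")
    d0 = (4 * r * dbar + 2 * dbar - 4) / (r * dbar - 2)
    if d0 <= 0:
        warnings.warn("negative moment solution for d0; returning infinity")
        return m1, float("inf")
    if d0 <= 4:
        warnings.warn("moment solution d0 <= 4: second moment of the "
                      "scaled-F marginal does not exist; estimate unstable")
    s0_sq = m1 * (d0 - 2) / d0
    return float(s0_sq), float(d0)


def _shrink_quasi_dispersion(s2, d, s0_sq, d0):
    """Posterior-mean shrinkage ``(d0 s0^2 + d s^2) / (d0 + d)``."""
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full(s2.shape, s0_sq)
    return (d0 * s0_sq + d * s2) / (d0 + d)


def ql_f_test(delta_dev, delta_df, phi_shrunk, d, d0):
    """Quasi-likelihood F-test.

    ``F = (delta_dev / delta_df) / phi_shrunk`` referred to
    ``F(delta_df, d0 + d)``; an infinite ``d0`` reduces the reference to
    the chi-square limit.
    """
    delta_dev = np.asarray(delta_dev, dtype=float)
    phi_shrunk = np.asarray(phi_shrunk, dtype=float)
    if np.any(phi_shrunk <= 0):
        raise ValueError("shrunk quasi-dispersions must be positive")
    F = np.clip(delta_dev, 0.0, None) / delta_df / phi_shrunk
    df2 = d0 + np.broadcast_to(np.asarray(d, dtype=float), F.shape)
    if np.isinf(d0):
        p = chi2.sf(F * delta_df, delta_df)
    else:
        p = f_dist.sf(F, delta_df, df2)
    return F, p


def _ql_test(an: DEAnalysis) -> DETestResult:
    cfg = an.config
    trend = (an.trend_smooth if cfg.ql_trend == "smooth"
             else an._trend(cfg.ql_trend))
    if cfg.fixed_dispersion is not None:
        omega = np.full(an.cm.n_genes, float(cfg.fixed_dispersion))
    else:
        omega = None
    ql = estimate_ql_dispersions(an.cm, trend, an.design, an.offsets,
                                 omega=omega,
                                 zero_df_correction=cfg.zero_df_correction)
    s0_sq, d0 = estimate_d0_s0(ql.s2[an.nonzero], ql.df_resid[an.nonzero],
                               method=cfg.d0_method)
    ql.s0_sq, ql.d0 = s0_sq, d0
    full, null = an._fits(ql.omega)
    null_dev = nb_deviance(an.cm.counts.astype(float), null["mu"],
                           ql.omega[:, None])
    delta = null_dev - ql.deviance
    F, p = ql_f_test(delta, 1.0, np.maximum(ql.phi_shrunk, 1e-12),
                     ql.df_resid, d0)
    return _assemble(an, "ql", full["beta"][:, 1], F, p, ql.omega)
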