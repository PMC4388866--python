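"""Negative-binomial regression on RNA-Seq count matrices.

The count for gene ``i`` in sample ``j`` is modelled as NB with mean
``mu_ij`` and dispersion ``phi_ij`` such that ``Var(Y) = mu + phi * mu**2``
(``size = 1/phi``; ``phi -> 0`` recovers Poisson).  The mean follows a
log-linear model with known per-sample offsets::

    log mu_ij = log(N_j) + log(R_j) + sum_k beta_ik X_jk

where ``N_j`` is the library size and ``R_j`` a pre-estimated normalization
factor.  This module provides the count-matrix container, low-expression
filtering, offset construction, IRLS fitting of the mean model at fixed
dispersion, the NB log-likelihood and the likelihood-ratio test.

All fitting routines are vectorised over genes: the design matrix is shared
across genes while dispersions may vary per gene (and per sample).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

# Dispersions below this are treated as exactly Poisson to avoid
# Gamma-function overflow in the NB mass.
POISSON_PHI_EPS = 1e-10

# IRLS controls (relative log-likelihood change).
IRLS_TOL = 1e-8
IRLS_MAXIT = 50

_MU_FLOOR = 1e-8
_ETA_CLIP = 50.0


# ---------------------------------------------------------------------------
# Count-matrix container
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A gene x sample matrix of read counts with sample annotations.

    Parameters
    ----------
    counts : (m, n) integer array of non-negative read counts.
    gene_ids, sample_ids : identifiers; generated if omitted.
    group : per-sample labels in {1, 2} (or all 1 for a single group).
    lib_size : per-sample library sizes ``N_j`` (default: column totals).
    norm_factor : per-sample normalization factors ``R_j`` (default 1).
    """

    counts: np.ndarray
    gene_ids: np.ndarray = None
    sample_ids: np.ndarray = None
    group: np.ndarray = None
    lib_size: np.ndarray = None
    norm_factor: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample matrix")
        m, n = self.counts.shape
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{i+1}" for i in range(m)])
        else:
            self.gene_ids = np.asarray(self.gene_ids)
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample{j+1}" for j in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.group is None:
            self.group = np.ones(n, dtype=int)
        else:
            self.group = np.asarray(self.group, dtype=int)
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_size = np.asarray(self.lib_size, dtype=float)
        if self.norm_factor is None:
            self.norm_factor = np.ones(n)
        else:
            self.norm_factor = np.asarray(self.norm_factor, dtype=float)
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ValueError("identifier lengths inconsistent with counts")
        if len(self.group) != n or len(self.lib_size) != n or len(self.norm_factor) != n:
            raise ValueError("per-sample annotation lengths inconsistent")
        if m > 0 and n > 0:
            if np.any(self.lib_size <= 0):
                raise ValueError("library sizes must be positive")
            if np.any(self.norm_factor <= 0):
                raise ValueError("normalization factors must be positive")
        if not np.all(np.isin(self.group, (1, 2))):
            raise ValueError("group labels must be in {1, 2}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, index) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[index],
            gene_ids=self.gene_ids[index],
            sample_ids=self.sample_ids,
            group=self.group,
            lib_size=self.lib_size,
            norm_factor=self.norm_factor,
        )

    # -- I/O: TSV with first column gene IDs, header = sample IDs -----------

    @classmethod
    def from_tsv(cls, path, group_path=None) -> "CountMatrix":
        """Read a count TSV (first column gene IDs, header sample IDs).

        ``group_path`` may point to a JSON object or a two-column TSV
        mapping sample ID to group label.
        """
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        group = None
        if group_path is not None:
            group = _read_group_map(group_path, df.columns)
        return cls(
            counts=df.to_numpy(),
            gene_ids=df.index.to_numpy(),
            sample_ids=df.columns.to_numpy(),
            group=group,
        )

    def to_tsv(self, path):
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.to_csv(path, sep="\t", index_label="gene_id")


def _read_group_map(path, sample_ids):
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            mapping = json.load(fh)
    else:
        tab = pd.read_csv(path, sep="\t", header=None, comment="#")
        mapping = dict(zip(tab.iloc[:, 0].astype(str), tab.iloc[:, 1]))
    return np.array([int(mapping[str(s)]) for s in sample_ids])


# ---------------------------------------------------------------------------
# Filtering and offsets
# ---------------------------------------------------------------------------

def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0,
                          min_samples: int = 1) -> CountMatrix:
    """Drop genes without ``cpm > min_cpm`` in at least ``min_samples`` samples.

    Counts per million use the raw column totals of the matrix at call
    time.  Library sizes of the result are recomputed from the retained
    genes.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = np.where(totals > 0, cm.counts / totals * 1e6, 0.0)
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("no genes pass the expression filter; returning an "
                      "empty count matrix")
    out = cm.subset_genes(keep)
    out.lib_size = out.counts.sum(axis=0).astype(float)
    return out


def make_offsets(cm: CountMatrix) -> np.ndarray:
    """Per-sample GLM offsets ``log(N_j) + log(R_j)``."""
    if np.any(cm.lib_size <= 0) or np.any(cm.norm_factor <= 0):
        raise ValueError("library sizes and normalization factors must be positive")
    return np.log(cm.lib_size) + np.log(cm.norm_factor)


def design_two_group(group) -> np.ndarray:
    """Intercept + group-2 indicator design; intercept-only if one group."""
    group = np.asarray(group)
    if np.all(group == group[0]):
        return np.ones((len(group), 1))
    return np.column_stack([np.ones(len(group)), (group == 2).astype(float)])


# ---------------------------------------------------------------------------
# NB log-likelihood
# ---------------------------------------------------------------------------

def nb_loglik(y, mu, phi):
    """Sum of NB(mu, phi) log-masses; Poisson limit taken below phi = 1e-10.

    Broadcasts over any common shape and reduces over all elements.
    """
    return float(np.sum(nb_loglik_terms(y, mu, phi)))


def nb_loglik_terms(y, mu, phi):
    """Elementwise NB log-masses (no reduction)."""
    y, mu, phi = np.broadcast_arrays(np.asarray(y, dtype=float),
                                     np.asarray(mu, dtype=float),
                                     np.asarray(phi, dtype=float))
    if np.any(phi < 0):
        raise ValueError("dispersions must be non-negative")
    mu = np.maximum(mu, 0.0)
    pois = phi < POISSON_PHI_EPS
    out = np.empty(y.shape, dtype=float)
    # Poisson branch
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = xlogy(yp, mp) - mp - gammaln(yp + 1)
    nb = ~pois
    if nb.any():
        yn, mn, pn = y[nb], mu[nb], phi[nb]
        k = 1.0 / pn
        out[nb] = (gammaln(yn + k) - gammaln(k) - gammaln(yn + 1)
                   + xlogy(k, k) - xlogy(k + yn, k + mn) + xlogy(yn, mn))
    return out


def nb_deviance(y, mu, phi):
    """Per-gene residual deviance ``2 * (ll_saturated - ll_fitted)``.

    ``y``/``mu``/``phi`` broadcast to (m, n); reduces over samples.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), y.shape)
    ll_fit = nb_loglik_terms(y, mu, phi)
    ll_sat = nb_loglik_terms(y, y, phi)
    return 2.0 * (ll_sat - ll_fit).sum(axis=1)


# ---------------------------------------------------------------------------
# IRLS fitting of the mean model at fixed dispersion
# ---------------------------------------------------------------------------

@dataclass
class MeanModelFit:
    """A fitted log-linear NB mean model for one gene."""
    design: np.ndarray
    beta: np.ndarray
    fitted_mu: np.ndarray
    offsets: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    phi: np.ndarray = field(default=None, repr=False)


def _closed_form_cells(X, offsets, phi):
    """Detect a saturated cell-means structure with a closed-form MLE.

    When the rows of ``[X | offset]`` take exactly ``p`` distinct values
    (e.g. a two-group design with equal offsets within groups) and the
    per-gene dispersion is constant across samples, the NB score equation
    within each cell forces ``mu_hat`` = cell mean of the counts, for any
    fixed dispersion.  Returns (labels, X_cells, off_cells) or None.
    """
    n, p = X.shape
    aug = np.column_stack([X, offsets])
    _, labels = np.unique(aug.round(12), axis=0, return_inverse=True)
    ncell = labels.max() + 1
    if ncell != p:
        return None
    X_cells = np.empty((p, p))
    off_cells = np.empty(p)
    for c in range(ncell):
        j = np.where(labels == c)[0][0]
        X_cells[c] = X[j]
        off_cells[c] = offsets[j]
    if abs(np.linalg.det(X_cells)) < 1e-12:
        return None
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 2 and phi.shape[1] > 1:
        if not np.allclose(phi, phi[:, :1]):
            return None
    return labels, X_cells, off_cells


def fit_nb_glm_matrix(counts, X, offsets, phi, beta0=None,
                      tol=IRLS_TOL, maxit=IRLS_MAXIT):
    """Fit the NB mean model to every gene at fixed dispersion.

    Parameters
    ----------
    counts : (m, n) counts.
    X : (n, p) full-rank design, shared across genes.
    offsets : (n,) per-sample log offsets.
    phi : dispersions, broadcastable to (m, n).

    Returns a dict with ``beta`` (m, p), ``mu`` (m, n), ``loglik`` (m,),
    ``converged`` (m,), ``iterations``.  Uses a closed-form cell-means
    solution for saturated designs, IRLS otherwise.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    m, n = counts.shape
    X = np.asarray(X, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), (n,))
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    phi_b = np.broadcast_to(np.asarray(phi, dtype=float), (m, n))

    cells = _closed_form_cells(X, offsets, np.asarray(phi, dtype=float))
    if cells is not None and beta0 is None:
        labels, X_cells, off_cells = cells
        mu_cells = np.empty((m, p))
        for c in range(p):
            mu_cells[:, c] = counts[:, labels == c].mean(axis=1)
        degenerate = (mu_cells <= 0).any(axis=1)
        mu_cells_f = np.maximum(mu_cells, _MU_FLOOR)
        eta_cells = np.log(mu_cells_f) - off_cells
        beta = np.linalg.solve(X_cells, eta_cells.T).T
        mu = mu_cells_f[:, labels]
        ll = nb_loglik_terms(counts, np.where(mu_cells[:, labels] > 0, mu, 0.0),
                             phi_b).sum(axis=1)
        return {
            "beta": beta, "mu": mu, "loglik": ll,
            "converged": ~degenerate,
            "iterations": np.ones(m, dtype=int),
        }

    # --- IRLS ---
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)
    if beta0 is None:
        z0 = np.log(counts + 0.5) - offsets
        beta = z0 @ XtX_inv_Xt.T
    else:
        beta = np.array(beta0, dtype=float)
        if beta.ndim == 1:
            beta = np.broadcast_to(beta, (m, p)).copy()
    eta = np.clip(offsets + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik_terms(counts, mu, phi_b).sum(axis=1)
    converged = np.zeros(m, dtype=bool)
    it = 0
    for it in range(1, maxit + 1):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi_b * mu)
        z = (eta - offsets) + (counts - mu) / np.maximum(mu, _MU_FLOOR)
        A = np.einsum("mn,nk,nl->mkl", w, X, X)
        b = np.einsum("mn,nk,mn->mk", w, X, z)
        A += 1e-10 * np.eye(p)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        beta = np.where(active[:, None], new_beta, beta)
        eta = np.clip(offsets + beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        new_ll = nb_loglik_terms(counts, mu, phi_b).sum(axis=1)
        delta = np.abs(new_ll - ll) / (np.abs(ll) + 1.0)
        converged = converged | (delta < tol)
        ll = new_ll
    allzero = (counts <= 0).all(axis=1)
    converged = converged & ~allzero
    return {"beta": beta, "mu": mu, "loglik": ll,
            "converged": converged, "iterations": np.full(m, it)}


def fit_nb_glm(y, X, offsets, phi) -> MeanModelFit:
    """Fit one gene's NB mean model at fixed dispersion (IRLS).

    ``phi`` may be a scalar or a per-sample vector; ``phi = 0`` gives the
    Poisson limit.  All-zero counts with an intercept-only design are
    reported as non-converged with fitted means pushed to zero.
    """
    y = np.asarray(y, dtype=float)
    res = fit_nb_glm_matrix(y[None, :], X, offsets, phi)
    return MeanModelFit(
        design=np.asarray(X, dtype=float),
        beta=res["beta"][0],
        fitted_mu=res["mu"][0],
        offsets=np.asarray(offsets, dtype=float),
        loglik=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
        iterations=int(res["iterations"][0]),
        phi=np.broadcast_to(np.asarray(phi, dtype=float), y.shape).copy(),
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio test
# ---------------------------------------------------------------------------

def lrt_from_logliks(ll_full, ll_null, df=1):
    """Vectorised LRT: statistic ``2(ll_full - ll_null)`` clipped at zero."""
    from scipy.stats import chi2
    ll_full = np.asarray(ll_full, dtype=float)
    ll_null = np.asarray(ll_null, dtype=float)
    raw = 2.0 * (ll_full - ll_null)
    if np.any(raw < -1e-6 * (1.0 + np.abs(ll_full))):
        warnings.warn("full-model log-likelihood below null beyond numerical "
                      "tolerance; fits may not be nested or converged")
    stat = np.clip(raw, 0.0, None)
    return stat, chi2.sf(stat, df)


def lrt_pvalue(fit_full: MeanModelFit, fit_null: MeanModelFit, df: int = 1):
    """Likelihood-ratio test of a nested null fit against the full fit."""
    stat, p = lrt_from_logliks(fit_full.loglik, fit_null.loglik, df)
    return float(stat), float(p)
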