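"""Seeded generators for synthetic two-group RNA-Seq experiments.

Counts are drawn ``Y_ij ~ NB(mu_ij, phi_ij)`` with

    log mu_ij  = log N_j + beta_i1 + beta_i2 * 1{group 2}        (R_j = 1)
    log phi_ij = f(log pi_ij; alpha) + eps_i,   eps_i ~ N(0, sigma^2)

where the trend predictor uses the *true* relative frequencies
``pi_ij = mu_ij / N_j`` (including any DE effect) and ``f`` defaults to a
log-quadratic (NBQ) trend.  A designated fraction of genes carries a
nonzero log fold change ``beta_i2`` — fixed at +/- log(FC) for exactly
half of the DE genes each, or taken from a supplied per-gene vector
("estimated" scheme).

One root seed expands into independent streams for baseline means, DE
designation, dispersion residuals and count draws, so changing sigma does
not perturb which genes are DE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nbcore import CountMatrix, design_two_group, make_offsets
from .dispersion import DispersionTrend, fit_trend, evaluate_trend

#: default NBQ trend coefficients on the centred log relative frequency.
#: The level corresponds to a biological CV of ~0.2 at the median
#: abundance (a human cell-line regime), falling with expression.
DEFAULT_TREND_ALPHA = (-3.2, -0.35, 0.05)

#: defaults for drawn baseline log mean counts (log scale)
DEFAULT_LOGMEAN_MU = 8.5
DEFAULT_LOGMEAN_SD = 1.5

_LOG_MU_CAP = 28.0  # overflow guard on the linear predictor


@dataclass
class SimulationSpec:
    """Complete recipe for a synthetic two-group experiment.

    ``fc_scheme`` is a fixed fold change (e.g. 1.2 or 1.5) or the string
    ``"estimated"``, in which case ``beta2`` supplies per-gene log fold
    changes (optionally permuted across the designated DE genes).
    ``trend`` may be a fitted :class:`DispersionTrend` or ``None`` to use
    the default NBQ coefficients (centred on the simulated predictor).
    """
    m: int = 5000
    group_sizes: tuple = (7, 7)
    lib_size: float = 2.5e7
    beta1: np.ndarray = None
    pi1: float = 0.1
    fc_scheme: object = 1.5
    beta2: np.ndarray = None
    permute_beta2: bool = False
    trend: DispersionTrend = None
    trend_alpha: tuple = DEFAULT_TREND_ALPHA
    sigma: float = 0.5
    logmean_mu: float = DEFAULT_LOGMEAN_MU
    logmean_sd: float = DEFAULT_LOGMEAN_SD
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0 <= self.pi1 <= 1:
            raise ValueError("DE fraction must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""
    is_de: np.ndarray
    true_logfc: np.ndarray
    true_phi: np.ndarray = field(repr=False)
    eps: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    trend: DispersionTrend = None


def _streams(seed, n=4):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_counts(rng, mu, phi):
    """NB draws via the size/prob parameterization; Poisson when phi ~ 0."""
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi < 1e-10
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_two_group(spec: SimulationSpec):
    """Generate a two-group count matrix with known truth.

    Returns ``(CountMatrix, SimTruth)``.
    """
    rng_beta, rng_de, rng_eps, rng_counts = _streams(spec.seed)
    n1, n2 = spec.group_sizes
    n = n1 + n2
    if n < 2:
        raise ValueError("need at least two samples")
    group = np.array([1] * n1 + [2] * n2)
    lib = np.broadcast_to(np.asarray(spec.lib_size, dtype=float), (n,)).copy()
    m = spec.m

    if spec.beta1 is None:
        logmu0 = rng_beta.normal(spec.logmean_mu, spec.logmean_sd, size=m)
        beta1 = logmu0 - np.log(lib.mean())
    else:
        beta1 = np.asarray(spec.beta1, dtype=float)
        if len(beta1) != m:
            raise ValueError("beta1 length must equal m")

    # DE designation and log fold changes
    m1 = int(round(spec.pi1 * m))
    is_de = np.zeros(m, dtype=bool)
    beta2 = np.zeros(m)
    de_idx = rng_de.choice(m, size=m1, replace=False)
    is_de[de_idx] = True
    if m1 > 0:
        if isinstance(spec.fc_scheme, str) and spec.fc_scheme == "estimated":
            if spec.beta2 is None:
                raise ValueError("estimated fc_scheme requires a beta2 vector")
            b2 = np.asarray(spec.beta2, dtype=float)
            vals = b2[de_idx]
            if spec.permute_beta2:
                vals = rng_de.permutation(vals)
            beta2[de_idx] = vals
        else:
            fc = float(spec.fc_scheme)
            n_up = m1 // 2
            signs = np.concatenate([np.ones(n_up), -np.ones(m1 - n_up)])
            beta2[de_idx] = signs * np.log(fc)

    log_mu = np.minimum(np.log(lib)[None, :] + beta1[:, None]
                        + beta2[:, None] * (group == 2)[None, :], _LOG_MU_CAP)
    mu = np.exp(log_mu)
    pi = mu / lib[None, :]

    trend = spec.trend
    if trend is None:
        alpha = np.asarray(spec.trend_alpha, dtype=float)
        trend = DispersionTrend(kind="nbq", alpha=alpha,
                                center=float(np.log(pi).mean()))
    eps = rng_eps.normal(0.0, spec.sigma, size=m) if spec.sigma > 0 else np.zeros(m)
    log_phi = trend.log_phi(pi) + eps[:, None]
    phi = np.exp(np.clip(log_phi, -40.0, 20.0))

    counts = _draw_counts(rng_counts, mu, phi)
    cm = CountMatrix(counts=counts, group=group, lib_size=lib)
    truth = SimTruth(is_de=is_de, true_logfc=beta2, true_phi=phi, eps=eps,
                     beta=np.column_stack([beta1, beta2]), trend=trend)
    return cm, truth


def simulate_single_group(m=5000, n=7, logmean_mu=DEFAULT_LOGMEAN_MU,
                          logmean_sd=DEFAULT_LOGMEAN_SD, trend=None,
                          trend_alpha=DEFAULT_TREND_ALPHA, sigma=0.5,
                          seed=0, lib_size=2.5e7):
    """Single-group replicates with log-normal baseline means.

    Per-gene means are drawn log-normal (mean ``logmean_mu``, SD
    ``logmean_sd`` on the log scale) and held constant across the ``n``
    replicates; dispersions follow the trend plus N(0, sigma^2) residuals.
    """
    spec = SimulationSpec(m=m, group_sizes=(n, 0), lib_size=lib_size,
                          pi1=0.0, trend=trend, trend_alpha=trend_alpha,
                          sigma=sigma, logmean_mu=logmean_mu,
                          logmean_sd=logmean_sd, seed=seed)
    return simulate_two_group(spec)


def extract_template(cm: CountMatrix, n_genes=5000, trend_kind="nbq",
                     seed=0):
    """Summarize a dataset into simulation ingredients.

    Randomly subsamples ``n_genes`` genes (all, with a warning, if fewer
    are available), fits per-gene two-group NB regressions at trend
    dispersions, the NBQ trend, and the residual-dispersion SD.  Returns
    ``(beta, trend, sigma_hat)`` where ``beta`` is (genes, 2) with the
    baseline log level and the log fold change.
    """
    from .nbcore import fit_nb_glm_matrix
    from .residvar import estimate_sigma

    rng = np.random.default_rng(seed)
    if cm.n_genes < n_genes:
        warnings.warn(f"only {cm.n_genes} genes available; using all")
        sub = cm
    else:
        idx = np.sort(rng.choice(cm.n_genes, size=n_genes, replace=False))
        sub = cm.subset_genes(idx)
    design = design_two_group(sub.group)
    offsets = make_offsets(sub)
    trend = fit_trend(sub, trend_kind, design, offsets)
    pi = trend.pi_gene
    pi_safe = np.where(np.isfinite(pi) & (pi > 0), pi, np.nanmedian(pi))
    phi = evaluate_trend(trend, pi_safe)
    fit = fit_nb_glm_matrix(sub.counts, design, offsets, phi[:, None])
    sig = estimate_sigma(sub, trend, design, offsets)
    beta = fit["beta"]
    if beta.shape[1] == 1:
        beta = np.column_stack([beta[:, 0], np.zeros(len(beta))])
    return beta, trend, sig.sigma_hat
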