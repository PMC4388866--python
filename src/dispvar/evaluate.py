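"""Power and FDR evaluation of DE tests against simulation truth.

Provides Benjamini-Hochberg adjustment, TPR-FDR curves (power against the
false discovery proportion as the ranking cutoff sweeps), actual-vs-
nominal FDR summaries, p-value uniformity diagnostics for the non-DE
genes, and the associated figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are passed through and excluded from the denominator.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class EvaluationResult:
    """TPR/FDR bookkeeping along a ranking of genes."""
    thresholds: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    fdr: np.ndarray = field(repr=False)
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    fn: np.ndarray = field(repr=False)
    tn: np.ndarray = field(repr=False)
    m: int = 0
    m1: int = 0

    def as_frame(self):
        return pd.DataFrame({"threshold": self.thresholds, "tpr": self.tpr,
                             "fdr": self.fdr, "tp": self.tp, "fp": self.fp,
                             "fn": self.fn, "tn": self.tn})


def tpr_fdr_curve(score, is_de, logfc=None) -> EvaluationResult:
    """Sweep the ranking cutoff and record TPR and FDR.

    ``score`` ranks genes (smaller = more significant, e.g. p-values);
    ties are broken by larger ``|logfc|``, then by gene index.  The FDR at
    zero discoveries is undefined and reported as NaN.
    """
    score = np.asarray(score, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    if score.shape != is_de.shape:
        raise ValueError("score and truth are misaligned")
    m = score.size
    m1 = int(is_de.sum())
    tie = -np.abs(logfc) if logfc is not None else np.zeros(m)
    order = np.lexsort((np.arange(m), tie, score))
    de_sorted = is_de[order]
    tp = np.concatenate([[0], np.cumsum(de_sorted)])
    disc = np.arange(m + 1)
    fp = disc - tp
    fn = m1 - tp
    tn = (m - m1) - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = tp / m1 if m1 > 0 else np.full(m + 1, np.nan)
        fdr = np.where(disc > 0, fp / np.maximum(disc, 1), np.nan)
    thresholds = np.concatenate([[-np.inf], score[order]])
    return EvaluationResult(thresholds=thresholds, tpr=np.asarray(tpr, dtype=float),
                            fdr=fdr, tp=tp, fp=fp, fn=fn, tn=tn, m=m, m1=m1)


def tpr_at_fdr(result: EvaluationResult, fdr_level: float) -> float:
    """Largest TPR attained at an actual FDR at or below ``fdr_level``."""
    ok = np.isfinite(result.fdr) & (result.fdr <= fdr_level)
    ok[0] = True  # zero discoveries trivially satisfy any level
    return float(np.max(result.tpr[ok]))


def actual_fdr_at_nominal(q, is_de, nominal: float = 0.10) -> float:
    """Realized FDR among genes with BH-adjusted ``q <= nominal``.

    NaN when there are no discoveries.
    """
    q = np.asarray(q, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    disc = np.isfinite(q) & (q <= nominal)
    if not disc.any():
        return float("nan")
    return float((~is_de[disc]).sum() / disc.sum())


def null_pvalue_diagnostics(p_null, bins: int = 20):
    """KS distance to Uniform(0,1) and a fixed-bin histogram of null p."""
    p_null = np.asarray(p_null, dtype=float)
    p_null = p_null[np.isfinite(p_null)]
    if p_null.size == 0:
        raise ValueError("no null p-values supplied")
    ks = kstest(p_null, "uniform").statistic
    hist, _ = np.histogram(p_null, bins=bins, range=(0.0, 1.0))
    return float(ks), hist


def ma_values(cm, logfc):
    """MA-plot coordinates: A = mean log2 cpm, M = log2 fold change."""
    cpm = cm.counts / cm.lib_size * 1e6
    A = np.log2(np.maximum(cpm, 0.5)).mean(axis=1)
    M = np.asarray(logfc, dtype=float) / np.log(2.0)
    return A, M


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    _, ax = plt.subplots()
    return ax


def plot_tpr_fdr(curves: dict, ax=None):
    """Overlay TPR-FDR curves; ``curves`` maps label -> EvaluationResult."""
    ax = _get_axes(ax)
    for label, res in curves.items():
        ax.plot(res.tpr, res.fdr, label=label)
    ax.set_xlabel("TPR")
    ax.set_ylabel("FDR")
    ax.legend(fontsize="small")
    return ax


def plot_null_pvalues(p_null, ax=None, bins: int = 20):
    ax = _get_axes(ax)
    ax.hist(np.asarray(p_null, dtype=float), bins=bins, range=(0, 1),
            density=True, edgecolor="white")
    ax.axhline(1.0, color="k", ls="--", lw=1)
    ax.set_xlabel("p-value (non-DE genes)")
    ax.set_ylabel("density")
    return ax


def plot_mean_dispersion(pi, phi_mom, trends: dict = None, ax=None):
    """MOM dispersions against relative mean frequency with trend overlays."""
    ax = _get_axes(ax)
    pi = np.asarray(pi, dtype=float)
    phi_mom = np.asarray(phi_mom, dtype=float)
    use = np.isfinite(pi) & (pi > 0) & np.isfinite(phi_mom) & (phi_mom > 0)
    ax.scatter(pi[use], phi_mom[use], s=3, alpha=0.25, color="gray")
    if trends:
        from .dispersion import evaluate_trend
        xs = np.geomspace(pi[use].min(), pi[use].max(), 200)
        for label, trend in trends.items():
            ax.plot(xs, evaluate_trend(trend, xs), label=label)
        ax.legend(fontsize="small")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("relative mean frequency")
    ax.set_ylabel("dispersion")
    return ax


def plot_calibration(cal, ax=None):
    """Calibration curve with replicate estimates and the inverted value."""
    ax = _get_axes(ax)
    for r in range(cal.sigma_hats.shape[1]):
        ax.scatter(cal.grid, cal.sigma_hats[:, r], s=12, color="gray")
    ax.scatter(cal.grid, cal.medians, s=30, color="tab:blue", zorder=3,
               label="median")
    xs = np.linspace(cal.grid.min(), cal.grid.max(), 100)
    c = cal.quad_coeffs
    ax.plot(xs, c[0] + c[1] * xs + c[2] * xs ** 2, color="tab:blue")
    ax.axvline(cal.sigma_tilde, color="tab:red", ls=":")
    ax.set_xlabel("generative sigma")
    ax.set_ylabel("estimated sigma")
    ax.legend(fontsize="small")
    return ax


def mean_dispersion_table(gene_ids, pi, phi_mom, trends: dict = None):
    """TSV-ready table of per-gene abundance, MOM dispersion and trends."""
    data = {"gene_id": gene_ids, "pi": pi, "phi_mom": phi_mom}
    if trends:
        from .dispersion import evaluate_trend
        pi_safe = np.where(np.isfinite(pi) & (pi > 0), pi, np.nan)
        for label, trend in trends.items():
            vals = np.full(len(pi), np.nan)
            ok = np.isfinite(pi_safe)
            vals[ok] = evaluate_trend(trend, pi_safe[ok])
            data[f"trend_{label}"] = vals
    return pd.DataFrame(data)
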