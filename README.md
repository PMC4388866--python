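# dispvar

Quantifying **residual dispersion variation** in negative-binomial models of
RNA-Seq counts, and measuring how it drives the power and FDR control of
differential-expression (DE) tests.

## The problem

Read counts from biological replicates are overdispersed relative to
Poisson: `Var(Y) = mu + phi * mu^2`, with a per-gene dispersion `phi`.
Because experiments have few replicates, most DE methods *pool* dispersion
information across genes through a mean-dispersion trend

```
log(phi_ij) = f(log pi_ij; alpha) + eps_i,      eps_i ~ N(0, sigma^2)
```

where `pi_ij = mu_ij / (N_j R_j)` is the relative mean frequency of gene
`i` in sample `j` and `f` is constant (common), log-linear (NBP),
log-quadratic (NBQ) or a nonparametric smooth.  The term `eps_i` is the
per-gene deviation the trend cannot explain.  `dispvar` estimates its
standard deviation `sigma` by maximum likelihood: each gene's conditional
likelihood in `eps` is integrated against the normal density using
Laplace's method, with the mean parameters handled by iteratively
reweighted least squares inside the integrand.  A simulation-based
**calibration** step inverts the estimator's bias, mapping the data
estimate `sigma_hat` to the generative value `sigma_tilde` that would
reproduce it.

Around that core the package provides NB regression and the
likelihood-ratio test, genewise / common / NBP / NBQ / smooth / tagwise
(empirical-Bayes shrinkage) dispersion estimators, the quasi-likelihood
F-test with its scaled-F prior-df machinery (`s_i^2 ~ s0^2 F(d_i, d0)`),
a seeded two-group count simulator with known truth, and TPR/FDR
evaluation utilities — everything needed to reproduce the finding that
the ranking of DE test strategies is governed by the magnitude of
`sigma`.

Intended users: statisticians and bioinformaticians studying DE-test
robustness, and method developers who need a transparent NB simulation
and evaluation harness.

## Worked example

```python
import numpy as np
from dispvar import (SimulationSpec, simulate_two_group, fit_trend,
                     estimate_sigma, de_test_many, actual_fdr_at_nominal)

cm, truth = simulate_two_group(SimulationSpec(
    m=2000, group_sizes=(7, 7), pi1=0.1, fc_scheme=1.5, sigma=0.9, seed=1))

trend = fit_trend(cm, "nbq")
est = estimate_sigma(cm, trend)
print(f"sigma_hat = {est.sigma_hat:.3f} (se {est.se:.3f}), "
      f"genes used = {est.n_genes_used}")

res = de_test_many(cm, ("genewise", "nbq", "ql"))
for method, r in res.items():
    fdr = actual_fdr_at_nominal(r.qvalue, truth.is_de, 0.10)
    print(f"{method:9s} actual FDR at nominal 10%: {fdr:.3f}")
```

Output:

```
sigma_hat = 0.978 (se 0.018), genes used = 2000
genewise  actual FDR at nominal 10%: 0.234
nbq       actual FDR at nominal 10%: 0.275
ql        actual FDR at nominal 10%: 0.095
```

The data were generated with `sigma = 0.9`; the estimate lands at 0.98
with a small standard error.  Because the residual dispersion variation
is large, the trend-only `nbq` test badly exceeds its nominal FDR (28%
actual at 10% nominal) and the genewise likelihood-ratio test is also
inflated at seven replicates per group, while the quasi-likelihood
F-test — which models per-gene dispersion variation and adjusts its
degrees of freedom — stays at nominal.

A command-line interface mirrors the library:

```bash
dispvar simulate --m 2000 --sigma 0.9 --seed 1 \
    --out-counts counts.tsv --out-truth truth.tsv
dispvar estimate-sigma --counts counts.tsv --trend nbq --out sigma.json
dispvar detest --counts counts.tsv --groups groups.json --method ql --out res.tsv
dispvar evaluate --results res.tsv --truth truth.tsv --out metrics.json
dispvar run-scenarios --config scenario.json   # the full factorial grid
```

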