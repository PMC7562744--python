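"""Gibbs-within-slice MCMC for the normal varying-intercept model.

The model: y_g ~ N(alpha[i_g], sigma); alpha_i ~ N(mu', sigma');
mu' ~ N(0, 1); sigma ~ Exp(1); sigma' ~ Exp(1).

alpha and mu' have conjugate normal full conditionals; sigma and sigma'
are updated by univariate slice sampling on the log scale (stepping-out
with shrinkage), which needs no tuning and leaves the exact joint density
invariant.
"""

from __future__ import annotations

import numpy as np


def slice_sample(logpdf, x0: float, rng, w: float = 0.5, max_steps: int = 50) -> float:
    """One update of a univariate slice sampler (Neal 2003, stepping-out)."""
    logy = logpdf(x0) + np.log(rng.uniform())
    u = rng.uniform(0.0, w)
    lo, hi = x0 - u, x0 + (w - u)
    for _ in range(max_steps):
        if logpdf(lo) < logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logpdf(hi) < logy:
            break
        hi += w
    while True:
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def run_chain(
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    *,
    draws: int,
    warmup: int,
    rng: np.random.Generator,
):
    """Run one MCMC chain; returns dict of posterior draws (post-warmup)."""
    counts = np.bincount(group_idx, minlength=n_groups).astype(float)
    sums = np.bincount(group_idx, weights=y, minlength=n_groups)
    group_means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    # jittered initialization from data summaries
    sigma = max(float(np.std(y)), 0.1) * np.exp(0.2 * rng.normal())
    alpha = group_means + 0.1 * rng.normal(size=n_groups)
    mu_p = float(np.mean(alpha)) + 0.1 * rng.normal()
    sigma_p = max(float(np.std(alpha)), 0.1) * np.exp(0.2 * rng.normal())

    n = len(y)
    k = n_groups
    out = {
        "alpha": np.empty((draws, k)),
        "mu_prime": np.empty(draws),
        "sigma_prime": np.empty(draws),
        "sigma": np.empty(draws),
    }
    for it in range(warmup + draws):
        # alpha_i | rest  (conjugate normal)
        prec = counts / sigma**2 + 1.0 / sigma_p**2
        mean = (sums / sigma**2 + mu_p / sigma_p**2) / prec
        alpha = mean + rng.normal(size=k) / np.sqrt(prec)
        # mu' | alpha  (N(0,1) prior)
        prec_mu = k / sigma_p**2 + 1.0
        mean_mu = (alpha.sum() / sigma_p**2) / prec_mu
        mu_p = mean_mu + rng.normal() / np.sqrt(prec_mu)
        # sigma | rest  (Exp(1) prior, slice on log sigma)
        resid2 = float(np.sum((y - alpha[group_idx]) ** 2))

        def lp_sigma(t):
            s = np.exp(t)
            return -n * t - resid2 / (2 * s**2) - s + t

        sigma = float(np.exp(slice_sample(lp_sigma, np.log(sigma), rng)))
        # sigma' | alpha, mu'
        dev2 = float(np.sum((alpha - mu_p) ** 2))

        def lp_sigma_p(t):
            s = np.exp(t)
            return -k * t - dev2 / (2 * s**2) - s + t

        sigma_p = float(np.exp(slice_sample(lp_sigma_p, np.log(sigma_p), rng)))
        if it >= warmup:
            j = it - warmup
            out["alpha"][j] = alpha
            out["mu_prime"][j] = mu_p
            out["sigma_prime"][j] = sigma_p
            out["sigma"][j] = sigma
    return out
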