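"""Numba Gibbs samplers for Bayesian whole-genome marker regressions.

All four models share the linear model ``y = mu + W a + e`` with
``e ~ N(0, I sigma_e^2)`` and differ in the marker-effect prior:

* BayesA   — ``a_j ~ N(0, s2_j)``, ``s2_j`` scaled-inverse-chi-square
  (a scaled-t marginal: every marker shrunk, heavy tails).
* BayesB   — point mass at zero with probability ``pi0`` plus the BayesA
  slab (per-marker variance).
* BayesCpi — point mass plus a common-variance Gaussian slab; the mixing
  proportion ``pi`` is sampled (Beta conjugate update).
* BL       — Bayesian LASSO: double-exponential marginal via the
  normal / exponential scale mixture with inverse-Gaussian updates.

Residual updates use single-site Gibbs with running residuals, the standard
economy for these samplers.  Samplers are jitted and seeded through numba's
``np.random.seed``, so a fixed seed reproduces the chain exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _sample_scaled_inv_chi2(df, scale_times_df):
    # scaled-inv-chi2(df, S): S*df / chi2(df)
    return scale_times_df / np.random.chisquare(df)


@njit(cache=False)
def _sample_inv_gaussian(mu, lam):
    v = np.random.normal() ** 2
    x = mu + (mu * mu * v) / (2.0 * lam) \
        - (mu / (2.0 * lam)) * np.sqrt(4.0 * mu * lam * v + mu * mu * v * v)
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=False)
def gibbs_sampler(W, y, model, iters, burnin, seed, pi0, nu_a, nu_e,
                  Sa_nu, Se_nu):
    """Run the Gibbs chain; returns (posterior mean effects, mean mu,
    posterior inclusion probabilities, mean sigma_e2).

    ``model``: 0 BayesA, 1 BayesB, 2 BayesCpi, 3 BL.
    ``Sa_nu`` and ``Se_nu`` are scale*df products for the slab and residual
    scaled-inverse-chi-square priors.
    """
    np.random.seed(seed)
    n, m = W.shape
    ww = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        ww[j] = s

    a = np.zeros(m)
    delta = np.ones(m)          # inclusion indicators (BayesB/Cpi)
    s2 = np.full(m, Sa_nu / nu_a)   # per-marker slab variances
    s2_common = Sa_nu / nu_a        # BayesCpi common slab variance
    tau2 = np.ones(m)               # BL scale mixture
    lam2 = 1.0                      # BL penalty^2
    pi_in = 1.0 - pi0
    mu = y.mean()
    e = y - mu
    sigma_e2 = Se_nu / nu_e

    sum_a = np.zeros(m)
    sum_pip = np.zeros(m)
    sum_mu = 0.0
    sum_se2 = 0.0
    kept = 0

    for it in range(iters):
        # --- mean
        e += mu
        mu = e.mean() + np.random.normal() * np.sqrt(sigma_e2 / n)
        e -= mu

        m_in = 0
        ssq_in = 0.0
        # --- marker effects
        for j in range(m):
            old = a[j]
            if old != 0.0:
                for i in range(n):
                    e[i] += W[i, j] * old
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * e[i]

            if model == 0:      # BayesA
                C = ww[j] + sigma_e2 / s2[j]
                mean = rhs / C
                new = mean + np.random.normal() * np.sqrt(sigma_e2 / C)
                s2[j] = _sample_scaled_inv_chi2(nu_a + 1.0, Sa_nu + new * new)
            elif model == 3:    # Bayesian LASSO
                C = ww[j] + 1.0 / tau2[j]
                mean = rhs / C
                new = mean + np.random.normal() * np.sqrt(sigma_e2 / C)
                mu_ig = np.sqrt(lam2 * sigma_e2 / (new * new + 1e-12))
                tau2[j] = 1.0 / _sample_inv_gaussian(mu_ig, lam2)
            else:               # BayesB / BayesCpi: spike and slab
                v = s2[j] if model == 1 else s2_common
                C = ww[j] + sigma_e2 / v
                log_odds = (np.log(pi_in / (1.0 - pi_in))
                            + 0.5 * np.log(sigma_e2 / (v * C))
                            + 0.5 * rhs * rhs / (C * sigma_e2))
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    mean = rhs / C
                    new = mean + np.random.normal() * np.sqrt(sigma_e2 / C)
                    delta[j] = 1.0
                    m_in += 1
                    ssq_in += new * new
                else:
                    new = 0.0
                    delta[j] = 0.0
                if model == 1:
                    aa = new * new if delta[j] == 1.0 else 0.0
                    dfj = nu_a + delta[j]
                    s2[j] = _sample_scaled_inv_chi2(dfj, Sa_nu + aa)

            a[j] = new
            if new != 0.0:
                for i in range(n):
                    e[i] -= W[i, j] * new

        # --- hyperparameters
        if model == 2:
            s2_common = _sample_scaled_inv_chi2(nu_a + m_in, Sa_nu + ssq_in)
            pi_in = np.random.beta(1.0 + m_in, 1.0 + (m - m_in))
            if pi_in < 1e-4:
                pi_in = 1e-4
            if pi_in > 1.0 - 1e-4:
                pi_in = 1.0 - 1e-4
        if model == 3:
            sum_tau2 = 0.0
            for j in range(m):
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(m + 1.0, 1.0 / (0.5 * sum_tau2 + 0.1))

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        if model == 3:
            # BL: effects scale with sigma_e; include their quadratic form
            qa = 0.0
            for j in range(m):
                qa += a[j] * a[j] / tau2[j]
            sigma_e2 = _sample_scaled_inv_chi2(nu_e + n + m, Se_nu + sse + qa)
        else:
            sigma_e2 = _sample_scaled_inv_chi2(nu_e + n, Se_nu + sse)
        if not np.isfinite(sigma_e2):
            raise ValueError("divergent chain")

        if it >= burnin:
            kept += 1
            sum_mu += mu
            sum_se2 += sigma_e2
            for j in range(m):
                sum_a[j] += a[j]
                sum_pip[j] += delta[j]

    return sum_a / kept, sum_mu / kept, sum_pip / kept, sum_se2 / kept
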