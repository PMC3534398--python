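"""Numba Gibbs-sampling kernels.

Both samplers share the linear model

    y = mu * 1 + s + X beta + e,        e ~ N(0, I sigma2_e)

with one record per sire, a polygenic effect s ~ N(0, A sigma2_s), and
marker effects beta under either a Bayesian-LASSO (double-exponential)
prior or a BayesC-pi point-mass mixture prior.

Because each sire contributes one record, rotating s into the
eigenbasis of A (A = U diag(d) U') makes its full conditional diagonal,
so the polygenic block is drawn exactly at O(n^2) cost per iteration.

Within-chain permutation (Che-Xu) is supported by physically reshuffling
the rows of X (and the running fitted marker values) against y every
``h_perm`` iterations, which preserves the y <-> A linkage while
destroying the genotype-phenotype one.

Residuals are maintained incrementally; genotype matrices should be
passed in Fortran order for contiguous column access.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NB = dict(cache=True, fastmath=True)


@njit(**_NB)
def _sample_scaled_inv_chi2(df, scale_times_df):
    """Draw from scaled-inv-chi2: scale_times_df / chi2(df)."""
    return scale_times_df / np.random.chisquare(df)


@njit(**_NB)
def _permute_rows(X, Xbuf, perm):
    n, p = X.shape
    for j in range(p):
        for i in range(n):
            Xbuf[i, j] = X[perm[i], j]


@njit(**_NB)
def blasso_chain(
    y,                # (n,) response, will be used as-is (center outside)
    X,                # (n, p) column-centered genotypes, Fortran order
    U,                # (n, n) eigenvectors of A, or (0, 0) if no polygenic
    d,                # (n,) eigenvalues of A (clipped > 0), or (0,)
    lam,              # lambda, > 0; ignored when sample_lambda
    sample_lambda,    # bool: sample lambda from its gamma full conditional
    a_lam, b_lam,     # gamma prior on lambda^2 (shape, rate)
    nu_e, s2_e,       # scaled-inv-chi2 prior for sigma2_e (df, scale)
    nu_s, s2_s,       # scaled-inv-chi2 prior for sigma2_s (df, scale)
    fixed_sigma2_e,   # > 0: hold sigma2_e at this value; <= 0: sample
    update_mu,        # bool
    n_iter, burn_in, thin,
    h_perm,           # 0: no permutation; else reshuffle X rows every h
    seed,
):
    """Run one Bayesian-LASSO Gibbs chain; returns stored samples.

    Returns (beta_store, mu_store, s2e_store, s2s_store, lam_store,
    s_store_var) where rows are the stored (post burn-in, thinned)
    samples.
    """
    np.random.seed(seed)
    n, p = X.shape
    use_poly = U.shape[0] > 0

    xtx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        xtx[j] = acc

    mu = 0.0
    beta = np.zeros(p)
    tau2 = np.ones(p)
    gam = np.zeros(n)           # rotated polygenic effect
    s = np.zeros(n)
    sigma2_e = fixed_sigma2_e if fixed_sigma2_e > 0.0 else np.var(y) * 0.5 + 1e-8
    sigma2_s = np.var(y) * 0.25 + 1e-8
    if sample_lambda:
        lam = np.sqrt(max(a_lam / b_lam, 1.0))

    r = y - mu - s              # residual (beta starts at zero)
    Xbuf = np.empty_like(X) if h_perm > 0 else np.empty((0, 0))
    perm = np.arange(n)
    fit = np.empty(n)           # scratch: fitted marker contribution

    # samples stored at iterations burn_in + thin, burn_in + 2*thin, ...
    n_store = (n_iter - burn_in) // thin
    beta_store = np.empty((n_store, p))
    mu_store = np.empty(n_store)
    s2e_store = np.empty(n_store)
    s2s_store = np.empty(n_store)
    lam_store = np.empty(n_store)

    k = 0
    for it in range(n_iter):
        if h_perm > 0 and it % h_perm == 0:
            # rows of X permute, so the fitted marker part (recovered
            # from the residual) permutes with them
            np.random.shuffle(perm)
            _permute_rows(X, Xbuf, perm)
            X, Xbuf = Xbuf, X
            for i in range(n):
                fit[i] = y[i] - mu - s[i] - r[i]
            for i in range(n):
                r[i] = y[i] - mu - s[i] - fit[perm[i]]

        if update_mu:
            acc = 0.0
            for i in range(n):
                acc += r[i] + mu
            mean = acc / n
            mu_new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / n)
            delta = mu - mu_new
            for i in range(n):
                r[i] += delta
            mu = mu_new

        # marker effects
        for j in range(p):
            if xtx[j] <= 0.0:
                beta[j] = 0.0
                continue
            b_old = beta[j]
            rhs = b_old * xtx[j]
            for i in range(n):
                rhs += X[i, j] * r[i]
            prec = xtx[j] + 1.0 / tau2[j]
            mean = rhs / prec
            b_new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / prec)
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * diff
            beta[j] = b_new

        # latent per-marker scales: 1/tau2_j ~ InvGauss
        lam2 = lam * lam
        for j in range(p):
            b2 = beta[j] * beta[j]
            if b2 < 1e-300:
                b2 = 1e-300
            mu_ig = np.sqrt(lam2 * sigma2_e / b2)
            if mu_ig > 1e8:
                mu_ig = 1e8
            inv_tau2 = np.random.wald(mu_ig, lam2)
            if inv_tau2 < 1e-12:
                inv_tau2 = 1e-12
            tau2[j] = 1.0 / inv_tau2

        # polygenic block, exact draw in the eigenbasis of A
        if use_poly:
            t = np.empty(n)
            for i in range(n):
                t[i] = r[i] + s[i]
            proj = U.T @ t
            for i in range(n):
                prec_i = 1.0 / sigma2_e + 1.0 / (d[i] * sigma2_s)
                m_i = (proj[i] / sigma2_e) / prec_i
                gam[i] = m_i + np.random.standard_normal() / np.sqrt(prec_i)
            s_new = U @ gam
            for i in range(n):
                r[i] = t[i] - s_new[i]
                s[i] = s_new[i]
            ss = 0.0
            for i in range(n):
                ss += gam[i] * gam[i] / d[i]
            sigma2_s = _sample_scaled_inv_chi2(nu_s + n, nu_s * s2_s + ss)

        # residual variance (beta prior is scaled by sigma2_e)
        if fixed_sigma2_e <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            sb = 0.0
            for j in range(p):
                sb += beta[j] * beta[j] / tau2[j]
            sigma2_e = _sample_scaled_inv_chi2(
                nu_e + n + p, nu_e * s2_e + sse + sb
            )

        if sample_lambda:
            st = 0.0
            for j in range(p):
                st += tau2[j]
            lam2_new = np.random.gamma(a_lam + p, 1.0 / (b_lam + 0.5 * st))
            lam = np.sqrt(lam2_new)

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            for j in range(p):
                beta_store[k, j] = beta[j]
            mu_store[k] = mu
            s2e_store[k] = sigma2_e
            s2s_store[k] = sigma2_s
            lam_store[k] = lam
            k += 1

    return beta_store, mu_store, s2e_store, s2s_store, lam_store


@njit(**_NB)
def bayescpi_chain(
    y,
    X,                # (n, p) column-centered, Fortran order
    U, d,             # eigensystem of A, or empty if no polygenic
    nu_e, s2_e,
    nu_s, s2_s,
    nu_b, s2_b,       # scaled-inv-chi2 prior for the common marker variance
    update_mu,
    n_iter, burn_in, thin,
    seed,
):
    """BayesC-pi Gibbs chain: point-mass-at-zero mixture prior on beta
    with a common non-null variance and a uniform prior on the null
    proportion pi.

    Returns (beta_store, delta_store, pi_store, s2e_store, s2b_store,
    mu_store).
    """
    np.random.seed(seed)
    n, p = X.shape
    use_poly = U.shape[0] > 0

    xtx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        xtx[j] = acc

    mu = 0.0
    beta = np.zeros(p)
    delta = np.zeros(p, dtype=np.int8)
    pi = 0.5
    gam = np.zeros(n)
    s = np.zeros(n)
    sigma2_e = np.var(y) * 0.5 + 1e-8
    sigma2_s = np.var(y) * 0.25 + 1e-8
    sigma2_b = s2_b

    r = y - mu  # beta and s start at zero

    # samples stored at iterations burn_in + thin, burn_in + 2*thin, ...
    n_store = (n_iter - burn_in) // thin
    beta_store = np.empty((n_store, p))
    delta_store = np.empty((n_store, p), dtype=np.int8)
    pi_store = np.empty(n_store)
    s2e_store = np.empty(n_store)
    s2b_store = np.empty(n_store)
    mu_store = np.empty(n_store)

    k = 0
    for it in range(n_iter):
        if update_mu:
            acc = 0.0
            for i in range(n):
                acc += r[i] + mu
            mean = acc / n
            mu_new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / n)
            dlt = mu - mu_new
            for i in range(n):
                r[i] += dlt
            mu = mu_new

        n_in = 0
        for j in range(p):
            if xtx[j] <= 0.0:
                continue
            b_old = beta[j]
            rhs = b_old * xtx[j]
            for i in range(n):
                rhs += X[i, j] * r[i]
            v1 = sigma2_e + sigma2_b * xtx[j]
            # log Bayes factor of inclusion vs exclusion
            log_bf = -0.5 * np.log(v1 / sigma2_e) + \
                0.5 * rhs * rhs * sigma2_b / (sigma2_e * v1)
            log_odds = np.log((1.0 - pi) / pi) + log_bf
            if log_odds > 35.0:
                p_in = 1.0
            elif log_odds < -35.0:
                p_in = 0.0
            else:
                p_in = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_in:
                prec = xtx[j] + sigma2_e / sigma2_b
                mean = rhs / prec
                b_new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / prec)
                delta[j] = 1
                n_in += 1
            else:
                b_new = 0.0
                delta[j] = 0
            diff = b_old - b_new
            if diff != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * diff
            beta[j] = b_new

        # common non-null effect variance
        ssb = 0.0
        for j in range(p):
            ssb += beta[j] * beta[j]
        sigma2_b = _sample_scaled_inv_chi2(nu_b + n_in, nu_b * s2_b + ssb)

        # null proportion, uniform prior
        pi = np.random.beta(p - n_in + 1.0, n_in + 1.0)

        if use_poly:
            t = np.empty(n)
            for i in range(n):
                t[i] = r[i] + s[i]
            proj = U.T @ t
            for i in range(n):
                prec_i = 1.0 / sigma2_e + 1.0 / (d[i] * sigma2_s)
                m_i = (proj[i] / sigma2_e) / prec_i
                gam[i] = m_i + np.random.standard_normal() / np.sqrt(prec_i)
            s_new = U @ gam
            for i in range(n):
                r[i] = t[i] - s_new[i]
                s[i] = s_new[i]
            ss = 0.0
            for i in range(n):
                ss += gam[i] * gam[i] / d[i]
            sigma2_s = _sample_scaled_inv_chi2(nu_s + n, nu_s * s2_s + ss)

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma2_e = _sample_scaled_inv_chi2(nu_e + n, nu_e * s2_e + sse)

        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            for j in range(p):
                beta_store[k, j] = beta[j]
                delta_store[k, j] = delta[j]
            pi_store[k] = pi
            s2e_store[k] = sigma2_e
            s2b_store[k] = sigma2_b
            mu_store[k] = mu
            k += 1

    return beta_store, delta_store, pi_store, s2e_store, s2b_store, mu_store
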