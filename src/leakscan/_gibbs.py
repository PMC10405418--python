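"""Single-site Gibbs sampler kernel for Bayesian whole-genome regression.

One compiled kernel covers Bayesian ridge regression (Gaussian prior on all
effects), BayesC (point mass at zero + common Gaussian slab) and BayesB
(point mass at zero + per-SNP scaled-t slab via per-SNP variances with
inverse-chi-square updates). The model is

    y = 1·mu + X·beta + e,   e ~ N(0, sigma2_e I)

with X column-centered by the caller. Residuals are maintained incrementally
so each SNP update costs O(n).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BRR, BAYESC, BAYESB = 0, 1, 2
MODEL_CODES = {"BRR": BRR, "BayesC": BAYESC, "BayesB": BAYESB}


@njit(cache=True, fastmath=True)
def gibbs_kernel(y, X, model, n_iter, burn_in, thin,
                 df_e, S_e, df_b, S_b, pi_a, pi_b, pi_fixed, seed):
    """Run the chain; returns posterior means and the thinned sigma2_e chain.

    pi_fixed < 0 means the inclusion proportion is sampled from its
    Beta(pi_a + k, pi_b + p_eff − k) full conditional; otherwise it is held
    fixed (pi_fixed = 1 with BayesC reduces the model to BRR).
    """
    np.random.seed(seed)
    n, p = X.shape
    xtx = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    active = xtx > 1e-12
    p_eff = int(active.sum())

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    beta = np.zeros(p)
    incl = np.ones(p, np.int8)
    sigma2_e = S_e * df_e / (df_e - 2.0) if df_e > 2 else S_e
    sigma2_b = S_b * df_b / (df_b - 2.0) if df_b > 2 else S_b
    sigma2_bj = np.full(p, sigma2_b)
    pi = 0.5 if pi_fixed < 0 else pi_fixed

    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - mu

    n_saved = (n_iter - burn_in + thin - 1) // thin
    se_chain = np.empty(n_saved)
    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    se_sum = 0.0
    sb_sum = 0.0
    pi_sum = 0.0
    saved = 0

    for it in range(n_iter):
        # intercept
        rbar = 0.0
        for i in range(n):
            rbar += r[i]
        rbar /= n
        mu_new = mu + rbar + np.sqrt(sigma2_e / n) * np.random.normal()
        shift = mu_new - mu
        for i in range(n):
            r[i] -= shift
        mu = mu_new

        k_in = 0
        ssb = 0.0  # sum of squared (included) effects for the common variance
        for j in range(p):
            if not active[j]:
                continue
            bj = beta[j]
            u = xtx[j] * bj
            for i in range(n):
                u += X[i, j] * r[i]
            if model == 0:  # BRR: always in
                C = xtx[j] + sigma2_e / sigma2_b
                bn = u / C + np.sqrt(sigma2_e / C) * np.random.normal()
                keep = True
            else:
                vj = sigma2_b if model == 1 else sigma2_bj[j]
                v0 = xtx[j] * sigma2_e
                v1 = xtx[j] * xtx[j] * vj + v0
                logbf = 0.5 * (np.log(v0 / v1) + u * u * (1.0 / v0 - 1.0 / v1))
                if pi >= 1.0:
                    keep = True
                elif pi <= 0.0:
                    keep = False
                else:
                    logodds = logbf + np.log(pi / (1.0 - pi))
                    if logodds > 35.0:
                        keep = True
                    elif logodds < -35.0:
                        keep = False
                    else:
                        keep = np.random.random() < 1.0 / (1.0 + np.exp(-logodds))
                if keep:
                    C = xtx[j] + sigma2_e / vj
                    bn = u / C + np.sqrt(sigma2_e / C) * np.random.normal()
                else:
                    bn = 0.0
            diff = bj - bn
            if diff != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * diff
            beta[j] = bn
            incl[j] = 1 if keep else 0
            if keep:
                k_in += 1
                ssb += bn * bn
            if model == 2:  # BayesB per-SNP variance
                if keep:
                    sigma2_bj[j] = (S_b * df_b + bn * bn) / np.random.chisquare(df_b + 1.0)
                else:
                    sigma2_bj[j] = S_b * df_b / np.random.chisquare(df_b)

        if model == 0:
            ss = 0.0
            for j in range(p):
                ss += beta[j] * beta[j]
            sigma2_b = (S_b * df_b + ss) / np.random.chisquare(df_b + p_eff)
        elif model == 1:
            sigma2_b = (S_b * df_b + ssb) / np.random.chisquare(df_b + k_in)
        if model != 0 and pi_fixed < 0:
            pi = np.random.beta(pi_a + k_in, pi_b + (p_eff - k_in))

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma2_e = (S_e * df_e + sse) / np.random.chisquare(df_e + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_sum += beta
            for j in range(p):
                incl_sum[j] += incl[j]
            mu_sum += mu
            se_sum += sigma2_e
            sb_sum += sigma2_b
            pi_sum += pi
            se_chain[saved] = sigma2_e
            saved += 1

    inv = 1.0 / saved
    return (beta_sum * inv, incl_sum * inv, mu_sum * inv,
            se_sum * inv, sb_sum * inv, pi_sum * inv, se_chain[:saved])
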