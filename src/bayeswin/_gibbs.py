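"""Numba kernels for the whole-genome regression Gibbs samplers.

Single-site Gibbs over the model  y = X beta + Z alpha + e  with a flat
prior on beta, one of two marker-effect priors (spike-and-slab with fixed
inclusion proportion pi, or the Laplace scale-mixture of the Bayesian
LASSO), and either a Gaussian likelihood or an ordinal probit likelihood
via liability augmentation (residual variance fixed at 1).

The residual vector ``e = y - X beta - Z alpha`` and the genetic value
vector ``g = Z alpha`` are maintained incrementally; the driver refreshes
them from scratch periodically to cancel float drift. All randomness goes
through numba's thread-local ``np.random`` state, seeded once per chain.
"""

import math

import numpy as np
from numba import njit

PRIOR_BAYESC = 0
PRIOR_BLASSO = 1
LIK_GAUSSIAN = 0
LIK_ORDINAL = 1

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def ndtri(p):
    """Inverse standard normal CDF (Acklam's rational approximation plus
    one Halley refinement; ~1e-15 absolute error on (1e-300, 1-1e-16))."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
              + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif p <= 1.0 - p_low:
        q = p - 0.5
        r = q * q
        x = (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
              - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
            (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
                - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
              - 1.328068155288572e+01) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                 - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
               + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    # Halley refinement
    err = _phi(x) - p
    u = err * _SQRT2PI * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def rand_truncnorm(mu, lo, hi):
    """One draw from N(mu, 1) truncated to (lo, hi]."""
    a = lo - mu
    b = hi - mu
    if b < a:
        return mu + 0.5 * (a + b)
    # far-tail cases: Robert's exponential rejection (inverse CDF underflows)
    if a > 5.0:
        for _ in range(200):
            z = a - math.log(1.0 - np.random.random()) / a
            if z <= b and np.random.random() <= math.exp(-0.5 * (z - a) ** 2):
                return mu + z
        return mu + min(a + 0.5 / a, 0.5 * (a + b))
    if b < -5.0:
        aa = -b
        bb = -a
        for _ in range(200):
            z = aa - math.log(1.0 - np.random.random()) / aa
            if z <= bb and np.random.random() <= math.exp(-0.5 * (z - aa) ** 2):
                return mu - z
        return mu - min(aa + 0.5 / aa, 0.5 * (aa + bb))
    pa = _phi(a) if a > -np.inf else 0.0
    pb = _phi(b) if b < np.inf else 1.0
    if pb - pa < 1e-14:
        lo2 = max(a, -6.0)
        hi2 = min(b, 6.0)
        return mu + 0.5 * (lo2 + hi2)
    u = pa + np.random.random() * (pb - pa)
    if u < 1e-300:
        u = 1e-300
    elif u > 1.0 - 1e-16:
        u = 1.0 - 1e-16
    return mu + ndtri(u)


@njit(cache=True)
def rand_scaled_inv_chi2(df, scale):
    """Scaled inverse chi-square draw: df*scale / chi2(df)."""
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def rand_invgauss(mu, lam):
    """Inverse-Gaussian(mu, lam) via Michael-Schucany-Haas.

    The smaller root is computed as mu * (sqrt(1+t) - 1) / (sqrt(1+t) + 1)
    with t = 4 lam / (mu y), which stays finite and positive for the very
    large mu that arise when an effect is shrunk towards zero (the naive
    quadratic-formula expression overflows and cancels catastrophically).
    """
    v = np.random.standard_normal()
    y = v * v
    if y <= 0.0:
        return mu
    t = 4.0 * lam / (mu * y)
    if t < 1e-12:  # sqrt(1+t) rounds to 1; use the series limits
        x = lam / y
    else:
        s = math.sqrt(1.0 + t)
        x = mu * (s - 1.0) / (s + 1.0)
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * (mu / x)


@njit(cache=True)
def bayesc_draw(r, czz, s2a, s2e, pi):
    """Spike-and-slab conditional draw for one marker.

    ``r = z_k' (residual with marker k's contribution restored)``. Returns
    (effect draw, inclusion indicator).
    """
    if czz <= 0.0:
        return 0.0, 0
    if pi >= 1.0:
        include = True
    elif pi <= 0.0:
        include = False
    else:
        v0 = czz * s2e
        v1 = v0 + czz * czz * s2a
        log_odds = math.log(pi / (1.0 - pi)) \
            + 0.5 * math.log(v0 / v1) \
            + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
        if log_odds > 35.0:
            include = True
        elif log_odds < -35.0:
            include = False
        else:
            include = np.random.random() < 1.0 / (1.0 + math.exp(-log_odds))
    if not include:
        return 0.0, 0
    prec = czz + s2e / s2a
    mean = r / prec
    sd = math.sqrt(s2e / prec)
    return mean + sd * np.random.standard_normal(), 1


@njit(cache=True)
def blasso_draw(r, czz, tau2, s2e):
    """Laplace scale-mixture conditional draw for one marker
    (effect prior N(0, tau2 * s2e) given its mixing variance)."""
    if czz <= 0.0:
        return 0.0
    prec = czz + 1.0 / tau2
    mean = r / prec
    sd = math.sqrt(s2e / prec)
    return mean + sd * np.random.standard_normal()


@njit(cache=True)
def update_liabilities_inplace(scores, y, e, cut, n_cat):
    """Redraw each latent liability from N(eta_i, 1) truncated to its
    score's interval; y and e are updated in place (eta_i = y_i - e_i)."""
    n = scores.shape[0]
    for i in range(n):
        c = scores[i]
        lo = cut[c - 2] if c >= 2 else -np.inf
        hi = cut[c - 1] if c <= n_cat - 1 else np.inf
        eta = y[i] - e[i]
        l_new = rand_truncnorm(eta, lo, hi)
        e[i] += l_new - y[i]
        y[i] = l_new


@njit(cache=True)
def update_cutpoints_inplace(scores, y, cut, n_cat):
    """Uniform conditional draw of each cutpoint between the largest
    liability of its lower category and the smallest liability above it.
    Empty categories fall back to the neighbouring occupied bounds; the
    draws stay ordered by construction."""
    prev = -np.inf
    for ci in range(n_cat - 1):
        lo = prev
        hi = np.inf
        for i in range(scores.shape[0]):
            c = scores[i]
            if c == ci + 1 and y[i] > lo:
                lo = y[i]
            elif c > ci + 1 and y[i] < hi:
                hi = y[i]
        if lo == -np.inf:
            lo = max(prev, min(hi - 1.0, cut[ci]))
        if hi == np.inf:
            hi = max(lo + 1.0, cut[ci])
        if hi <= lo:
            hi = lo + 1e-12
        cut[ci] = lo + np.random.random() * (hi - lo)
        prev = cut[ci]


@njit(cache=True)
def _update_fixed_effects(Xt, cxx, e, beta, s2e):
    p, n = Xt.shape
    for j in range(p):
        if cxx[j] <= 0.0:
            continue
        r = cxx[j] * beta[j]
        for i in range(n):
            r += Xt[j, i] * e[i]
        mean = r / cxx[j]
        new = mean + math.sqrt(s2e / cxx[j]) * np.random.standard_normal()
        d = new - beta[j]
        for i in range(n):
            e[i] -= Xt[j, i] * d
        beta[j] = new


@njit(cache=True, fastmath=True)
def _snp_sweep(prior, Zt, czz, e, g, alpha, delta, tau2, pi, s2a, s2e):
    """One pass over all markers; returns (n_included, sum of squared
    included effects) for the hyperparameter updates."""
    m, n = Zt.shape
    n_incl = 0
    sse = 0.0
    for k in range(m):
        a_old = alpha[k]
        r = czz[k] * a_old
        zk = Zt[k]
        for i in range(n):
            r += zk[i] * e[i]
        if prior == PRIOR_BAYESC:
            a_new, d = bayesc_draw(r, czz[k], s2a, s2e, pi)
            delta[k] = d
            if d == 1:
                n_incl += 1
                sse += a_new * a_new
        else:
            a_new = blasso_draw(r, czz[k], tau2[k], s2e)
            delta[k] = 1
        if a_new != a_old:
            diff = a_old - a_new
            for i in range(n):
                e[i] += zk[i] * diff
                g[i] -= zk[i] * diff
            alpha[k] = a_new
    return n_incl, sse


@njit(cache=True)
def _update_blasso_hyper(alpha, tau2, lambda2, s2e, bl_shape, bl_rate):
    """Update the mixing variances tau2 and lambda2; returns the new
    lambda2 and sum alpha_k^2 / tau2_k at the refreshed tau2 (needed by
    the sigma2_e conditional, which conditions on the current tau2)."""
    m = alpha.shape[0]
    sum_tau2 = 0.0
    sum_a2_over_tau2 = 0.0
    for k in range(m):
        a2 = alpha[k] * alpha[k]
        if a2 < 1e-24:
            # mu' -> infinity limit of the inverse-Gaussian conditional is
            # the Levy(lambda2) law: 1/tau2 = lambda2 / chi2_1
            z = np.random.standard_normal()
            inv = lambda2 / max(z * z, 1e-12)
        else:
            mu = math.sqrt(lambda2 * s2e / a2)
            inv = rand_invgauss(mu, lambda2)
        tau2[k] = 1.0 / min(max(inv, 1e-300), 1e300)
        sum_tau2 += tau2[k]
        sum_a2_over_tau2 += a2 / tau2[k]
    return draw_lambda2(m, sum_tau2, bl_shape, bl_rate), sum_a2_over_tau2


@njit(cache=True)
def draw_lambda2(m, sum_tau2, bl_shape, bl_rate):
    """Gamma full conditional for the LASSO shrinkage parameter lambda^2."""
    shape = bl_shape + m
    rate = bl_rate + 0.5 * sum_tau2
    return np.random.gamma(shape, 1.0 / rate)


@njit(cache=True)
def gibbs_sweep(likelihood, prior, scores, y, Xt, cxx, Zt, czz,
                e, g, beta, alpha, delta, tau2, cut, n_cat,
                pi, s2a, nu_a, scale_a, fix_s2a,
                s2e, nu_e, scale_e, fix_s2e,
                lambda2, bl_shape, bl_rate, sample_cut=True):
    """One full Gibbs cycle; mutates state arrays, returns updated
    (s2a, s2e, lambda2)."""
    n = y.shape[0]
    if likelihood == LIK_ORDINAL:
        update_liabilities_inplace(scores, y, e, cut, n_cat)
        if sample_cut:
            update_cutpoints_inplace(scores, y, cut, n_cat)
    _update_fixed_effects(Xt, cxx, e, beta, s2e)
    n_incl, sse = _snp_sweep(prior, Zt, czz, e, g, alpha, delta, tau2,
                             pi, s2a, s2e)
    sum_a2_over_tau2 = 0.0
    if prior == PRIOR_BAYESC:
        if fix_s2a <= 0.0:
            s2a = rand_scaled_inv_chi2(nu_a + n_incl,
                                       (nu_a * scale_a + sse) / (nu_a + n_incl))
    else:
        lambda2, sum_a2_over_tau2 = _update_blasso_hyper(
            alpha, tau2, lambda2, s2e, bl_shape, bl_rate)
    if likelihood == LIK_GAUSSIAN and fix_s2e <= 0.0:
        ss = 0.0
        for i in range(n):
            ss += e[i] * e[i]
        if prior == PRIOR_BLASSO:
            # the Laplace scale mixture puts s2e inside the effect prior,
            # so the conditional gains m degrees of freedom and the
            # alpha^2 / tau2 sum
            m = alpha.shape[0]
            df = nu_e + n + m
            s2e = rand_scaled_inv_chi2(
                df, (nu_e * scale_e + ss + sum_a2_over_tau2) / df)
        else:
            s2e = rand_scaled_inv_chi2(nu_e + n,
                                       (nu_e * scale_e + ss) / (nu_e + n))
    return s2a, s2e, lambda2


@njit(cache=True)
def _refresh_state(y, Xt, Zt, beta, alpha, e, g):
    """Recompute e and g from scratch (float drift control)."""
    n = y.shape[0]
    for i in range(n):
        acc = 0.0
        for j in range(Xt.shape[0]):
            acc += Xt[j, i] * beta[j]
        gg = 0.0
        for k in range(Zt.shape[0]):
            gg += Zt[k, i] * alpha[k]
        g[i] = gg
        e[i] = y[i] - acc - gg


@njit(cache=True)
def _popvar(v):
    n = v.shape[0]
    mean = 0.0
    for i in range(n):
        mean += v[i]
    mean /= n
    acc = 0.0
    for i in range(n):
        d = v[i] - mean
        acc += d * d
    return acc / n


@njit(cache=True)
def run_chain(seed, likelihood, prior, scores, y0, Xt, Zt, cut0, n_cat,
              pi, nu_a, scale_a, fix_s2a, nu_e, scale_e, fix_s2e,
              bl_shape, bl_rate,
              n_iter, burn_in, thin, store_alpha, sample_cut=True):
    """Run a full chain; returns posterior accumulators and retained chains.

    Returns (alpha_mean, incl_freq, beta_mean, cut_mean,
             s2snp_chain, s2e_chain, hyper_chain, alpha_chain, status)
    where hyper_chain holds sigma2_alpha draws (spike-slab) or lambda2
    draws (LASSO) and status is 0 on success, 1 on divergence.
    """
    np.random.seed(seed)
    m, n = Zt.shape
    p = Xt.shape[0]

    y = y0.copy()
    cut = cut0.copy()
    beta = np.zeros(p)
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    tau2 = np.ones(m)
    e = y.copy()
    g = np.zeros(n)

    cxx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += Xt[j, i] * Xt[j, i]
        cxx[j] = acc
    czz = np.empty(m)
    for k in range(m):
        acc = 0.0
        for i in range(n):
            acc += Zt[k, i] * Zt[k, i]
        czz[k] = acc

    s2e = 1.0 if likelihood == LIK_ORDINAL else \
        (fix_s2e if fix_s2e > 0.0 else max(_popvar(y), 1e-8))
    s2a = fix_s2a if fix_s2a > 0.0 else max(scale_a, 1e-8)
    lambda2 = bl_shape / max(bl_rate, 1e-300) if bl_rate > 0.0 else 1.0

    n_keep = 0
    for it in range(n_iter):
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
    alpha_mean = np.zeros(m)
    incl_freq = np.zeros(m)
    beta_mean = np.zeros(p)
    cut_mean = np.zeros(cut.shape[0])
    s2snp_chain = np.zeros(n_keep)
    s2e_chain = np.zeros(n_keep)
    hyper_chain = np.zeros(n_keep)
    if store_alpha:
        alpha_chain = np.zeros((n_keep, m))
    else:
        alpha_chain = np.zeros((1, m))

    kept = 0
    status = 0
    for it in range(n_iter):
        s2a, s2e, lambda2 = gibbs_sweep(
            likelihood, prior, scores, y, Xt, cxx, Zt, czz,
            e, g, beta, alpha, delta, tau2, cut, n_cat,
            pi, s2a, nu_a, scale_a, fix_s2a,
            s2e, nu_e, scale_e, fix_s2e,
            lambda2, bl_shape, bl_rate, sample_cut)
        if not (math.isfinite(s2e) and math.isfinite(s2a)
                and math.isfinite(lambda2)) or s2e > 1e12:
            status = 1
            break
        if (it + 1) % 1000 == 0:
            _refresh_state(y, Xt, Zt, beta, alpha, e, g)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in range(m):
                alpha_mean[k] += alpha[k]
                incl_freq[k] += delta[k]
            for j in range(p):
                beta_mean[j] += beta[j]
            for ci in range(cut.shape[0]):
                cut_mean[ci] += cut[ci]
            s2snp_chain[kept] = _popvar(g)
            s2e_chain[kept] = s2e
            hyper_chain[kept] = s2a if prior == PRIOR_BAYESC else lambda2
            if store_alpha:
                for k in range(m):
                    alpha_chain[kept, k] = alpha[k]
            kept += 1

    if kept > 0:
        for k in range(m):
            alpha_mean[k] /= kept
            incl_freq[k] /= kept
        for j in range(p):
            beta_mean[j] /= kept
        for ci in range(cut.shape[0]):
            cut_mean[ci] /= kept
    return (alpha_mean, incl_freq, beta_mean, cut_mean,
            s2snp_chain[:kept], s2e_chain[:kept], hyper_chain[:kept],
            alpha_chain[:kept] if store_alpha else alpha_chain[:0],
            status)
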