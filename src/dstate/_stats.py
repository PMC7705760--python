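"""Shared numerical machinery: NB likelihoods, IRLS fits, empirical Bayes.

The negative binomial is parameterized throughout as var = mu + phi * mu^2
(edgeR convention); phi = 0 is the Poisson limit.  The empirical-Bayes
variance machinery (log-variance moment matching of a scaled-F prior,
trigamma inversion, trend via lowess) follows the standard moderated-variance
construction used by bulk RNA-seq engines.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

_PHI_FLOOR = 1e-8
_PHI_CEIL = 100.0


# ---------------------------------------------------------------------------
# negative binomial log-likelihood and deviance
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """Elementwise NB log-pmf with mean ``mu`` and dispersion ``phi``.

    Falls back to the Poisson log-pmf where ``phi`` is (near) zero.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), np.broadcast_shapes(y.shape, np.shape(phi)))
    out = np.empty(np.broadcast_shapes(y.shape, mu.shape, phi_arr.shape), dtype=float)
    y, mu, phi_arr = np.broadcast_arrays(y, mu, phi_arr)
    pois = phi_arr < 1e-10
    if np.any(pois):
        yp, mp = y[pois], mu[pois]
        out[pois] = yp * np.log(mp) - mp - gammaln(yp + 1)
    if np.any(~pois):
        yn, mn, pn = y[~pois], mu[~pois], phi_arr[~pois]
        r = 1.0 / pn
        out[~pois] = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        )
    return out


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """Rowwise NB residual deviance, 2 * (loglik(saturated) - loglik(mu))."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    small = phi < 1e-10
    r = 1.0 / np.maximum(phi, 1e-10)
    term2_nb = (y + r) * np.log((1.0 + phi * y) / (1.0 + phi * mu))
    term2 = np.where(np.broadcast_to(small, term2_nb.shape), y - mu, term2_nb)
    dev = 2.0 * (term1 - term2)
    return dev.sum(axis=-1)


def estimate_dispersion_grid(
    y: np.ndarray,
    mu: np.ndarray,
    n_grid: int = 60,
    phi_min: float = _PHI_FLOOR,
    phi_max: float = _PHI_CEIL,
    cr_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Per-row ML dispersion with means held fixed, via a log-phi grid.

    Evaluates the NB profile log-likelihood on a common log-spaced grid for
    all rows at once and refines the argmax with one parabolic interpolation
    step in log(phi).  Rows whose likelihood is maximized at the lower edge
    get phi = 0 (Poisson).

    With ``cr_labels`` (a group label per column) the likelihood is Cox-Reid
    adjusted for the estimated group means: 0.5 * log det(X'WX) is
    subtracted, which for a groupwise design is 0.5 * sum_g log sum_{c in g}
    w_c with w = mu / (1 + phi * mu).  This removes the downward bias of the
    plug-in ML when the sample count is small.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    G = y.shape[0]
    grid = np.logspace(np.log10(phi_min), np.log10(phi_max), n_grid)
    ll = np.empty((G, n_grid))
    groups = None
    if cr_labels is not None:
        labels = np.asarray(cr_labels)
        groups = [labels == u for u in np.unique(labels)]
    # constant-in-phi pieces are kept: only argmax matters and they cancel
    for j, phi in enumerate(grid):
        ll[:, j] = nb_loglik(y, mu, phi).sum(axis=-1)
        if groups is not None:
            w = mu / (1.0 + phi * mu)
            for m in groups:
                ll[:, j] -= 0.5 * np.log(np.maximum(w[:, m].sum(axis=-1), 1e-300))
    best = np.argmax(ll, axis=1)
    log_grid = np.log(grid)
    phi_hat = grid[best]
    interior = (best > 0) & (best < n_grid - 1)
    if np.any(interior):
        i = np.where(interior)[0]
        b = best[i]
        x0, x1, x2 = log_grid[b - 1], log_grid[b], log_grid[b + 1]
        y0, y1, y2 = ll[i, b - 1], ll[i, b], ll[i, b + 1]
        denom = (y0 - 2 * y1 + y2)
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = 0.5 * (y0 - y2) / denom
        shift = np.where(np.abs(denom) > 1e-12, np.clip(shift, -1.0, 1.0), 0.0)
        step = x1 - x0
        phi_hat[i] = np.exp(x1 + shift * step)
    phi_hat = np.where(best == 0, 0.0, phi_hat)
    return np.clip(phi_hat, 0.0, phi_max)


# ---------------------------------------------------------------------------
# NB GLM: two-group (or intercept-only) fit with offsets, vectorized over genes
# ---------------------------------------------------------------------------


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Fisher-scoring fit of per-gene NB GLMs with a shared design matrix.

    ``y`` is genes x samples, ``design`` samples x p (p <= 2), ``offsets``
    log library sizes per sample, ``phi`` per-gene dispersion.  Returns
    (coefficients genes x p, fitted means genes x samples).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    G, S = y.shape
    p = X.shape[1]
    phi = np.asarray(phi, dtype=float).reshape(G, 1)
    # initialize from adjusted log means
    beta = np.zeros((G, p))
    lib = np.exp(offsets)
    beta[:, 0] = np.log(np.maximum((y + 0.5).sum(axis=1) / (lib.sum() + 1.0), 1e-12))
    eta = offsets[None, :] + beta @ X.T
    mu = np.exp(np.clip(eta, -700, 700))
    for _ in range(max_iter):
        W = mu / (1.0 + phi * mu)  # Fisher weights for log link
        z = (eta - offsets[None, :]) + (y - mu) / np.maximum(mu, 1e-300)
        # per-gene weighted least squares, p x p normal equations
        XtWX = np.einsum("gs,sp,sq->gpq", W, X, X)
        XtWz = np.einsum("gs,sp,gs->gp", W, X, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        new_beta = np.clip(new_beta, -50, 50)
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = offsets[None, :] + beta @ X.T
        mu = np.exp(np.clip(eta, -700, 700))
        if delta < tol:
            break
    return beta, mu


# ---------------------------------------------------------------------------
# TMM normalization factors
# ---------------------------------------------------------------------------


def tmm_norm_factors(
    y: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors for a count matrix.

    ``y`` is genes x samples.  Each sample is compared to the reference
    column (upper quartile of CPM closest to the mean upper quartile); the
    weighted mean of the doubly trimmed log-ratios gives its factor.  The
    factors are scaled to multiply to 1; effective library sizes are
    ``column sums * factors``.  Robust to a minority of strongly
    differential genes contaminating the raw library sizes.
    """
    y = np.asarray(y, dtype=float)
    lib = y.sum(axis=0)
    S = y.shape[1]
    if np.any(lib <= 0):
        return np.ones(S)
    uq = np.array([np.quantile(y[:, s][y[:, s] > 0] / lib[s], 0.75) if (y[:, s] > 0).any() else 0 for s in range(S)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(S)
    yr, Nr = y[:, ref], lib[ref]
    for s in range(S):
        if s == ref:
            continue
        ys, Ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        ps, pr = ys[ok] / Ns, yr[ok] / Nr
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        w = (Ns - ys[ok]) / (Ns * ys[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        n = M.size
        lo_m, hi_m = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(A, [sum_trim, 1 - sum_trim])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            continue
        f = (M[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
        factors[s] = 2.0 ** f
    # geometric mean 1
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# trends and empirical Bayes
# ---------------------------------------------------------------------------


def lowess_trend(x: np.ndarray, y: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Lowess fit of y on x, evaluated at the input x (in input order)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 5 or np.ptp(x[ok]) < 1e-12:
        out = np.full_like(x, np.nan)
        out[:] = np.nanmean(y[ok]) if ok.any() else np.nan
        return out
    fitted = _sm_lowess(y[ok], x[ok], frac=frac, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]
    return np.interp(x, xs, ys)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float, covariate: np.ndarray | None = None):
    """Moment-match s2 ~ s0^2 * F(df, d0) on the log scale.

    Returns (d0, s0_squared) where ``s0_squared`` is a scalar or, when a
    covariate is given, a per-gene trend.  ``d0`` may be ``inf`` when the
    observed log-variance spread is no larger than chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.full_like(s2, np.nan)
    z[ok] = np.log(s2[ok])
    e = z - float(digamma(df / 2.0)) + np.log(df / 2.0)
    if covariate is not None:
        e_mu = lowess_trend(np.asarray(covariate, float)[ok], e[ok])
        e_mu_full = np.interp(
            np.asarray(covariate, float),
            np.sort(np.asarray(covariate, float)[ok]),
            e_mu[np.argsort(np.asarray(covariate, float)[ok])],
        )
    else:
        e_mu_full = np.full_like(e, np.nanmean(e[ok]))
    resid = e[ok] - e_mu_full[ok]
    n = resid.size
    if n < 2:
        return np.inf, np.exp(np.nanmean(e_mu_full))
    evar = resid.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = np.exp(e_mu_full + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(e_mu_full)
    return d0, s0


def squeeze_var(
    s2: np.ndarray,
    df: float,
    covariate: np.ndarray | None = None,
    prior_df: float | None = None,
):
    """Empirical-Bayes posterior variances (moderated toward the prior).

    ``prior_df`` overrides the moment-matched d0 (0 disables moderation,
    ``inf`` replaces every variance by the prior trend).  Returns
    (s2_post, d0, s2_prior).
    """
    d0, s2_prior = fit_f_dist(s2, df, covariate)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0.0:
            s2 = np.asarray(s2, dtype=float)
            return s2.copy(), 0.0, np.broadcast_to(np.asarray(s2_prior, float), s2.shape).copy()
    s2_prior = np.broadcast_to(np.asarray(s2_prior, float), np.shape(s2)).copy()
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        post = s2_prior.copy()
    else:
        post = (d0 * s2_prior + df * s2) / (d0 + df)
    bad = ~np.isfinite(s2)
    post[bad] = s2_prior[bad]
    return post, d0, s2_prior
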