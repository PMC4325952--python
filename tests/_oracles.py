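"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: a plain IRLS ridge
logistic regression, and a Metropolis-within-Gibbs sampler (elliptical slice
sampling for the whitened field) for the dense-covariance spatial logistic
model.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

from spatmiss.matern import MaternParams, dense_covariance


def irls_penalised_logistic(X, y, precision=0.001, max_iter=200, tol=1e-12):
    """Maximum a posteriori logistic regression with an independent
    N(0, 1/precision) prior on every coefficient (including intercept).
    ``X`` should already contain the intercept column."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (p - y) + precision * beta
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + precision * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def mcmc_spatial_logit(
    locations,
    X,
    y,
    hyper_means,
    hyper_precision=1.0,
    regression_precision=0.001,
    n_iter=100_000,
    burn=20_000,
    thin=10,
    seed=123,
):
    """Long-run sampler for the dense-field spatial logistic model.

    The latent field is whitened (u = L(θ) v with v ~ N(0, I)) so that the
    hyperparameter update leaves v invariant, and v is updated by elliptical
    slice sampling, which is rejection-free for a Gaussian prior.  Returns
    an array of (α, β, log κ, log τ) samples.
    """
    locations = np.asarray(locations, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)

    def chol_for(lk, lt):
        p = MaternParams.from_kappa_tau(math.exp(lk), math.exp(lt))
        c = dense_covariance(locations, p)
        return np.linalg.cholesky(c + 1e-10 * np.eye(n))

    def loglik(alpha, beta, Lv):
        e = alpha + beta * X + Lv
        return float(np.sum(y * e - np.logaddexp(0, e)))

    alpha, beta = 0.0, 0.0
    lk, lt = hyper_means
    Lc = chol_for(lk, lt)
    v = rng.standard_normal(n)
    Lv = Lc @ v
    ll = loglik(alpha, beta, Lv)
    pr = regression_precision
    hp = hyper_precision
    samples = []
    for it in range(n_iter):
        a2 = alpha + 0.4 * rng.standard_normal()
        ll2 = loglik(a2, beta, Lv)
        if math.log(rng.random()) < (ll2 - ll) + 0.5 * pr * (
            alpha**2 - a2**2
        ):
            alpha, ll = a2, ll2
        b2 = beta + 0.3 * rng.standard_normal()
        ll2 = loglik(alpha, b2, Lv)
        if math.log(rng.random()) < (ll2 - ll) + 0.5 * pr * (beta**2 - b2**2):
            beta, ll = b2, ll2
        lk2 = lk + 0.25 * rng.standard_normal()
        lt2 = lt + 0.25 * rng.standard_normal()
        Lc2 = chol_for(lk2, lt2)
        Lv2 = Lc2 @ v
        ll2 = loglik(alpha, beta, Lv2)
        dprior = -0.5 * hp * (
            (lk2 - hyper_means[0]) ** 2 + (lt2 - hyper_means[1]) ** 2
        ) + 0.5 * hp * (
            (lk - hyper_means[0]) ** 2 + (lt - hyper_means[1]) ** 2
        )
        if math.log(rng.random()) < (ll2 - ll) + dprior:
            lk, lt, Lc, Lv, ll = lk2, lt2, Lc2, Lv2, ll2
        # elliptical slice update of the whitened field
        nu = rng.standard_normal(n)
        logu = ll + math.log(rng.random())
        th = rng.uniform(0, 2 * math.pi)
        thmin, thmax = th - 2 * math.pi, th
        while True:
            v2 = v * math.cos(th) + nu * math.sin(th)
            Lv2 = Lc @ v2
            ll2 = loglik(alpha, beta, Lv2)
            if ll2 > logu:
                v, Lv, ll = v2, Lv2, ll2
                break
            if th < 0:
                thmin = th
            else:
                thmax = th
            th = rng.uniform(thmin, thmax)
        if it >= burn and it % thin == 0:
            samples.append((alpha, beta, lk, lt))
    return np.array(samples)
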