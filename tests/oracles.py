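"""Independent reference computations used by the tests.

These deliberately avoid the package's own numerical paths: the bivariate
normal CDF here is built from Owen's T function (scipy.special.owens_t),
and the polychoric "oracle" maximises the same contingency-table
log-likelihood by brute-force grid search instead of Brent's method.
"""

import numpy as np
from scipy.special import ndtr, owens_t
from scipy.stats import norm


def bvn_cdf_ref(h, k, rho):
    """P(X<=h, Y<=k) via Owen's T; rho may be an array in (-1, 1)."""
    rho = np.asarray(rho, dtype=float)
    if np.isinf(h) or np.isinf(k):
        if h == -np.inf or k == -np.inf:
            return np.zeros_like(rho)
        if h == np.inf and k == np.inf:
            return np.ones_like(rho)
        finite = k if np.isinf(h) else h
        return np.full_like(rho, ndtr(finite))
    # Owen's formula is singular at exact zeros; nudge off the axis
    if h == 0.0:
        h = 1e-12
    if k == 0.0:
        k = 1e-12
    den = np.sqrt(1.0 - rho ** 2)
    ah = (k - rho * h) / (h * den)
    ak = (h - rho * k) / (k * den)
    beta = 0.5 if (h * k < 0 or (h * k == 0 and h + k < 0)) else 0.0
    return 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta


def margin_cuts(margin):
    """Threshold cut vector (with sentinels) from marginal counts."""
    margin = np.asarray(margin, dtype=float)
    cum = np.cumsum(margin) / margin.sum()
    return np.concatenate([[-np.inf], norm.ppf(np.clip(cum[:-1], 0, 1)),
                           [np.inf]])


def grid_oracle_rho(table, step=1e-4, lo=-0.99, hi=0.99):
    """Brute-force ML estimate of the polychoric correlation.

    Evaluates the two-step log-likelihood on a dense rho grid and returns
    the grid argmax.
    """
    table = np.asarray(table, dtype=float)
    cuts_a = margin_cuts(table.sum(axis=1))
    cuts_b = margin_cuts(table.sum(axis=0))
    rho = np.arange(lo, hi + step / 2, step)
    ra, rb = table.shape
    F = {}
    for i in range(ra + 1):
        for j in range(rb + 1):
            F[i, j] = bvn_cdf_ref(cuts_a[i], cuts_b[j], rho)
    ll = np.zeros_like(rho)
    for i in range(ra):
        for j in range(rb):
            n = table[i, j]
            if n > 0:
                P = F[i + 1, j + 1] - F[i, j + 1] - F[i + 1, j] + F[i, j]
                ll += n * np.log(np.clip(P, 1e-12, None))
    return float(rho[np.argmax(ll)])


def random_table(rng, size, n=500):
    """Random C x C contingency table with dependence between margins.

    Regenerates until every row and column category holds at least five
    observations, so the two-step likelihood has well-separated
    thresholds and a unique interior maximum.
    """
    while True:
        rho = rng.uniform(-0.9, 0.9)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        cuts_a = np.sort(rng.uniform(-1.6, 1.6, size - 1))
        cuts_b = np.sort(rng.uniform(-1.6, 1.6, size - 1))
        a = np.searchsorted(cuts_a, z[:, 0])
        b = np.searchsorted(cuts_b, z[:, 1])
        table = np.zeros((size, size))
        np.add.at(table, (a, b), 1.0)
        if table.sum(axis=1).min() >= 5 and table.sum(axis=0).min() >= 5:
            return table
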