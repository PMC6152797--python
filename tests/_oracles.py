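"""Independent brute-force oracles used to validate the fitting code.

These deliberately avoid the package's optimization path: the decay oracle
is an exhaustive grid search over (Th, eff), the Wilcoxon oracle enumerates
all sign assignments, and the line-fit oracle is the closed-form OLS slope.
"""

from itertools import product

import numpy as np


def grid_search_decay(t, y, th_range=(0.1, 600.0), eff_range=(0.01, 1.0),
                      n_th=3000, n_eff=400):
    """Exhaustive SS minimization of eff*2**(-t/Th)+(1-eff) over a dense grid."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    th_grid = np.exp2(np.linspace(np.log2(th_range[0]), np.log2(th_range[1]), n_th))
    eff_grid = np.linspace(eff_range[0], eff_range[1], n_eff)
    X = np.power(2.0, -t[None, :] / th_grid[:, None]) - 1.0
    sxx = (X ** 2).sum(axis=1)
    sxy = (X * (y - 1.0)).sum(axis=1)
    syy = float(((y - 1.0) ** 2).sum())
    ss = syy - 2.0 * eff_grid[None, :] * sxy[:, None] + (eff_grid ** 2)[None, :] * sxx[:, None]
    i, j = np.unravel_index(np.argmin(ss), ss.shape)
    return float(th_grid[i]), float(eff_grid[j]), float(ss[i, j])


def golden_section_fixed_eff(t, y, eff, th_range=(0.1, 600.0), tol=1e-12):
    """1-D golden-section minimization of SS over log2(Th) at fixed eff."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)

    def ss(g):
        r = y - (eff * np.power(2.0, -t / np.exp2(g)) + 1.0 - eff)
        return float(r @ r)

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log2(th_range[0]), np.log2(th_range[1])
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    while b - a > tol:
        if ss(c) < ss(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    return float(np.exp2((a + b) / 2.0))


def wilcoxon_enumerate(d):
    """Exact two-sided signed-rank p by enumerating all 2**n sign vectors."""
    d = np.asarray(d, float)
    d = d[d != 0.0]
    n = len(d)
    ranks = _rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    count = 0
    total = 2 ** n
    for signs in product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def _rankdata(x):
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    ranks[order] = np.arange(1, len(x) + 1)
    for v in np.unique(x):
        m = x == v
        ranks[m] = ranks[m].mean()
    return ranks


def ols_slope(t, y):
    """Closed-form OLS slope and intercept."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm, ym = t.mean(), y.mean()
    slope = float(((t - tm) * (y - ym)).sum() / ((t - tm) ** 2).sum())
    return slope, float(ym - slope * tm)
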