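"""Independent oracles used by the test suite.

Each routine recomputes a quantity by a deliberately different route from
the package implementation: brute-force lattice search for the decay fit,
array splitting for burst segmentation, exhaustive label permutation for
the two-sample test, and the raw covariance formula for Pearson r.
"""

import itertools
from functools import lru_cache

import numpy as np


def grid_search_exp_decay(x, y, n_grid=100):
    """Minimize SSE of alpha*exp(-x/beta)+eps over an n_grid^3 lattice.

    The lattice spans a broad box around moment-based center values and
    returns (alpha, beta, eps, sse) at the best lattice point.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    eps0 = y.min()
    alpha0 = max(y.max() - eps0, 1e-12)
    beta0 = max(np.average(x, weights=np.maximum(y, 1e-12)), 1e-6)
    alphas = np.linspace(0.2 * alpha0, 3.0 * alpha0, n_grid)
    betas = np.linspace(0.3 * beta0, 3.0 * beta0, n_grid)
    epss = np.linspace(eps0 - 0.5 * alpha0, eps0 + 0.5 * alpha0, n_grid)

    # SSE(a,b,e) = Syy - 2a*S1(b) - 2e*Sy + a^2*S2(b) + 2ae*S3(b) + k*e^2
    E = np.exp(-x[None, :] / betas[:, None])  # (Nb, k)
    S1 = E @ y
    S2 = (E * E).sum(axis=1)
    S3 = E.sum(axis=1)
    Sy = y.sum()
    Syy = (y * y).sum()
    k = x.size
    a = alphas[:, None, None]
    b_S1 = S1[None, :, None]
    b_S2 = S2[None, :, None]
    b_S3 = S3[None, :, None]
    e = epss[None, None, :]
    sse = Syy - 2 * a * b_S1 - 2 * e * Sy + a**2 * b_S2 + 2 * a * e * b_S3 + k * e**2
    i, j, m = np.unravel_index(np.argmin(sse), sse.shape)
    steps = (alphas[1] - alphas[0], betas[1] - betas[0], epss[1] - epss[0])
    box = ((alphas[0], alphas[-1]), (betas[0], betas[-1]), (epss[0], epss[-1]))
    return (alphas[i], betas[j], epss[m], float(sse[i, j, m]), steps, box)


def split_runs(times, threshold):
    """Maximal-run segmentation via array splitting at large gaps."""
    times = np.asarray(times, float)
    if times.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(times) >= threshold) + 1
    return [seg for seg in np.split(times, cuts)]


@lru_cache(maxsize=8)
def _split_indices(n_total, n_a):
    return np.array(list(itertools.combinations(range(n_total), n_a)))


def permutation_p_two_sided(a, b):
    """Exact permutation p-value using the Welch t statistic on every split."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    data = np.concatenate([a, b])
    na, nb = a.size, b.size
    idx = _split_indices(data.size, na)
    sel = data[idx]
    tot, ss_tot = data.sum(), (data**2).sum()
    ma = sel.mean(axis=1)
    sa = sel.sum(axis=1)
    mb = (tot - sa) / nb
    va = sel.var(axis=1, ddof=1)
    vb = (ss_tot - (sel**2).sum(axis=1) - nb * mb**2) / (nb - 1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    t_obs = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / na + b.var(ddof=1) / nb)
    return float(np.mean(np.abs(t) >= abs(t_obs) - 1e-12))


def pearson_r_covariance(x, y):
    """r from the raw covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
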