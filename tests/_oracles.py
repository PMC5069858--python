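"""Independent brute-force references used by the test suite.

Everything here is written directly from the model definitions with
naive numerics (explicit sums, dense grids, finite differences) and
never calls into the package's probability or estimation code, so it can
serve as an oracle for it.
"""

from __future__ import annotations

import numpy as np


def grm_probs(a, thresholds, theta, D=1.0):
    """Graded-response category probabilities via boundary logistics."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(thresholds, dtype=float)
    cum = 1.0 / (1.0 + np.exp(-D * a * (th[:, None] - b[None, :])))
    cum = np.concatenate(
        [np.ones((th.size, 1)), cum, np.zeros((th.size, 1))], axis=1)
    return cum[:, :-1] - cum[:, 1:]


def gpcm_probs(a, steps, theta, D=1.0):
    """Partial-credit category probabilities via naive exponent sums."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    d = np.asarray(steps, dtype=float)
    K = d.size + 1
    num = np.empty((th.size, K))
    for k in range(K):
        s = np.zeros(th.size)
        for j in range(k):
            s += D * a * (th - d[j])
        num[:, k] = np.exp(s)
    return num / num.sum(axis=1, keepdims=True)


def item_probs(item, theta, D=1.0):
    """Dispatch on an ItemParameters-like object (model, a, thresholds)."""
    if item.model == "GRM":
        return grm_probs(item.a, item.thresholds, theta, D)
    return gpcm_probs(item.a, item.thresholds, theta, D)


def pattern_loglik(items_and_cats, theta, D=1.0):
    """Sum of log category probabilities over (item, category) pairs."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    ll = np.zeros(th.size)
    for item, cat in items_and_cats:
        p = item_probs(item, th, D)[:, cat]
        ll += np.log(np.clip(p, 1e-300, None))
    return ll


def _grid(lo=-6.0, hi=6.0, n=10_001):
    return np.linspace(lo, hi, n)


def eap_dense(items_and_cats, D=1.0, mean=0.0, var=1.0, n=10_001,
              lo=-6.0, hi=6.0):
    """Posterior mean and SD on a dense grid under a normal prior."""
    grid = _grid(lo, hi, n)
    logpost = pattern_loglik(items_and_cats, grid, D)
    logpost = logpost - 0.5 * (grid - mean) ** 2 / var
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    m = float(np.sum(grid * post))
    sd = float(np.sqrt(np.sum((grid - m) ** 2 * post)))
    return m, sd


def _parabolic_argmax(grid, values):
    """Grid argmax refined by fitting a parabola through the peak."""
    i = int(np.argmax(values))
    if i == 0 or i == grid.size - 1:
        return float(grid[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(grid[i])
    offset = 0.5 * (y0 - y2) / denom
    h = grid[1] - grid[0]
    return float(grid[i] + offset * h)


def map_dense(items_and_cats, D=1.0, mean=0.0, var=1.0, n=10_001,
              lo=-6.0, hi=6.0):
    """Posterior mode by dense-grid maximization with parabolic refinement."""
    grid = _grid(lo, hi, n)
    obj = pattern_loglik(items_and_cats, grid, D) \
        - 0.5 * (grid - mean) ** 2 / var
    return _parabolic_argmax(grid, obj)


def ml_dense(items_and_cats, D=1.0, n=10_001, lo=-6.0, hi=6.0):
    """Likelihood maximum by dense-grid search with parabolic refinement."""
    grid = _grid(lo, hi, n)
    obj = pattern_loglik(items_and_cats, grid, D)
    return _parabolic_argmax(grid, obj)


def _fd_prob_derivs(item, theta, D=1.0, h=1e-5):
    """Finite-difference first and second derivatives of P_k(theta)."""
    p0 = item_probs(item, theta, D)
    pp = item_probs(item, np.asarray(theta) + h, D)
    pm = item_probs(item, np.asarray(theta) - h, D)
    dp = (pp - pm) / (2 * h)
    d2p = (pp - 2 * p0 + pm) / h ** 2
    return p0, dp, d2p


def wle_dense(items_and_cats, D=1.0, n=10_001, lo=-6.0, hi=6.0):
    """Root of the Warm-corrected score by dense sign-change bracketing.

    score, test information I and companion J are all assembled from
    finite-difference derivatives of the naive probability functions.
    """
    grid = _grid(lo, hi, n)
    g = np.zeros(grid.size)
    info = np.zeros(grid.size)
    comp = np.zeros(grid.size)
    for item, cat in items_and_cats:
        p, dp, d2p = _fd_prob_derivs(item, grid, D)
        psafe = np.clip(p, 1e-300, None)
        g += dp[:, cat] / psafe[:, cat]
        info += np.sum(dp * dp / psafe, axis=1)
        comp += np.sum(dp * d2p / psafe, axis=1)
    f = g + comp / (2 * np.clip(info, 1e-300, None))
    down = np.where((f[:-1] > 0) & (f[1:] <= 0))[0]
    if down.size == 0:
        return float(grid[np.argmin(np.abs(f))])
    # several downward crossings are possible; rank them by the
    # antiderivative of f (the integrated weighted objective) and keep
    # the global maximum
    step = grid[1] - grid[0]
    cumW = np.concatenate([[0.0], np.cumsum(0.5 * (f[:-1] + f[1:]) * step)])
    i = int(down[np.argmax(cumW[down])])
    # linear interpolation of the crossing
    x0, x1, f0, f1 = grid[i], grid[i + 1], f[i], f[i + 1]
    return float(x0 - f0 * (x1 - x0) / (f1 - f0))


def sumscore_eap_enumeration(items, D=1.0, mean=0.0, var=1.0,
                             n_nodes=101, lo=-6.0, hi=6.0):
    """EAP-by-total-score via exhaustive pattern enumeration.

    For every total score s, sums the likelihoods of all response
    patterns with that total on the quadrature grid, then takes the
    posterior mean.  Exponential in the number of items; for tiny
    item sets only.
    """
    import itertools

    grid = np.linspace(lo, hi, n_nodes)
    w = np.exp(-0.5 * (grid - mean) ** 2 / var)
    w /= w.sum()
    max_score = sum(it.thresholds.__len__() for it in items)
    like_by_score = np.zeros((max_score + 1, n_nodes))
    ranges = [range(len(it.thresholds) + 1) for it in items]
    for cats in itertools.product(*ranges):
        L = np.exp(pattern_loglik(list(zip(items, cats)), grid, D))
        like_by_score[sum(cats)] += L
    out = []
    for s in range(max_score + 1):
        post = like_by_score[s] * w
        post /= post.sum()
        m = float(np.sum(grid * post))
        sd = float(np.sqrt(np.sum((grid - m) ** 2 * post)))
        out.append((m, sd))
    return out
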