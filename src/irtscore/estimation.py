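"""Person-parameter (theta) estimation with fixed item parameters.

Five estimators are provided, mirroring the scoring choices of the
common-metric application this package reimplements:

``EAP``
    posterior mean of theta given the full response pattern, by
    quadrature over an equally spaced grid (default 101 nodes on
    [-6, 6]); the standard error is the posterior SD.  Always finite.
``EAPsum``
    posterior mean given only the total raw score of one complete
    instrument; the score distribution at each node is built by the
    Lord-Wingersky convolution recursion over items.
``MAP``
    posterior mode (Bayes modal), by safeguarded Newton; SE from the
    curvature of the log posterior at the mode.
``ML``
    maximum likelihood; diverges for all-lowest / all-highest response
    patterns, which are flagged ``DIVERGED`` with missing estimates.
    SE = 1/sqrt(test information) at the estimate.
``WLE``
    Warm's weighted likelihood estimator: the root of
    ``score(theta) + J(theta) / (2 I(theta))``, which removes the
    leading-order ML bias and stays finite at extreme patterns.

Priors are normal on the theta scale: standard N(0,1), diffuse N(0,10)
(variance 10), or empirical — a normal whose mean and variance are
estimated from the sample by an EM marginal-maximum-likelihood step with
all item parameters held fixed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import MISSING, ItemParameters, MetricBank, ResponseMatrix
from .models import (
    PROB_FLOOR,
    category_prob_derivs,
    category_probs,
    item_information,
    item_information_companion,
    log_category_probs,
    log_likelihood,
    score_function,
    test_information,
)

__all__ = [
    "Prior", "QuadratureGrid", "ScoreEstimate",
    "make_grid", "pattern_loglik_matrix",
    "estimate_eap_pattern", "sumscore_table", "estimate_eap_sumscore",
    "estimate_map", "estimate_ml", "estimate_wle",
    "estimate_prior_from_data", "score_table",
    "ESTIMATORS",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS: tuple[float, float] = (-6.0, 6.0)
DEFAULT_NODES: int = 101

# flag names
ALL_MISSING = "ALL_MISSING"
DIVERGED = "DIVERGED"
AT_BOUND = "AT_BOUND"
INCOMPLETE_FOR_SUMSCORE = "INCOMPLETE_FOR_SUMSCORE"

ESTIMATORS = ("EAP", "EAPsum", "MAP", "WLE", "ML")


@dataclass(frozen=True)
class Prior:
    """Normal latent-trait prior on the theta scale.

    ``kind`` is ``"standard"`` (N(0,1)), ``"diffuse"`` (N(0,10), i.e.
    variance 10) or ``"empirical"`` (parameters estimated from data by
    :func:`estimate_prior_from_data`).
    """

    kind: str
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "diffuse", "empirical"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not (self.variance > 0):
            raise ValueError("prior variance must be > 0")
        if self.kind == "standard" and (self.mean, self.variance) != (0.0, 1.0):
            raise ValueError("standard prior is N(0,1)")
        if self.kind == "diffuse" and (self.mean, self.variance) != (0.0, 10.0):
            raise ValueError("diffuse prior is N(0,10)")

    @classmethod
    def standard(cls) -> "Prior":
        return cls("standard", 0.0, 1.0)

    @classmethod
    def diffuse(cls) -> "Prior":
        return cls("diffuse", 0.0, 10.0)

    @classmethod
    def empirical(cls, mean: float, variance: float) -> "Prior":
        return cls("empirical", float(mean), float(variance))

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def log_density(self, theta) -> np.ndarray:
        th = np.asarray(theta, dtype=float)
        return (-0.5 * (th - self.mean) ** 2 / self.variance
                - 0.5 * math.log(2 * math.pi * self.variance))


@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced theta nodes with normalized prior mass."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be 1-D and aligned")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)


def make_grid(
    prior: Prior,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> QuadratureGrid:
    """Equally spaced nodes on ``bounds`` weighted by the prior density."""
    if n_nodes < 11:
        raise ValueError("need at least 11 quadrature nodes")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    nodes = np.linspace(lo, hi, n_nodes)
    weights = np.exp(prior.log_density(nodes))
    return QuadratureGrid(nodes=nodes, weights=weights)


@dataclass(frozen=True)
class ScoreEstimate:
    """One respondent's theta estimate.

    ``theta_hat`` and ``se`` are NaN when missing (all responses missing,
    or a diverged/undefined estimate); ``flags`` says why.
    """

    theta_hat: float
    se: float
    estimator: str
    n_items_answered: int
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.theta_hat)


def _as_pattern(pattern) -> dict[str, int]:
    if isinstance(pattern, Mapping):
        return {c: int(v) for c, v in pattern.items() if int(v) != MISSING}
    raise TypeError("pattern must be a mapping of item code -> category")


# ---------------------------------------------------------------------------
# Grid likelihood machinery

def pattern_loglik_matrix(
    responses: ResponseMatrix, bank: MetricBank, nodes: np.ndarray
) -> np.ndarray:
    """Log-likelihood of every row at every node, shape (n_rows, n_nodes).

    Missing cells contribute nothing, so rows with arbitrary missingness
    are handled uniformly.
    """
    nodes = np.asarray(nodes, dtype=float)
    out = np.zeros((responses.n_rows, nodes.size))
    for j, code in enumerate(responses.codes):
        item = bank.item(code)
        logp = log_category_probs(item, nodes, bank.scaling_D)  # (n_nodes, K)
        col = responses.data[:, j]
        answered = col != MISSING
        if answered.any():
            out[answered] += logp[:, col[answered]].T
    return out


def _posterior_moments(
    loglik: np.ndarray, grid: QuadratureGrid
) -> tuple[float, float]:
    """Posterior mean and SD of theta from log-likelihood values at nodes."""
    logpost = loglik + np.log(grid.weights)
    logpost = logpost - logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    mean = float(np.sum(grid.nodes * post))
    var = float(np.sum((grid.nodes - mean) ** 2 * post))
    return mean, math.sqrt(max(var, 0.0))


def estimate_eap_pattern(
    pattern: Mapping[str, int],
    bank: MetricBank,
    prior: Prior | None = None,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> ScoreEstimate:
    """Expected-a-posteriori estimate from a full response pattern.

    Always exists: an all-missing pattern returns the prior mean and
    prior SD, flagged ``ALL_MISSING``.
    """
    prior = prior or Prior.standard()
    pat = _as_pattern(pattern)
    if not pat:
        return ScoreEstimate(prior.mean, prior.sd, "EAP", 0,
                             frozenset({ALL_MISSING}))
    grid = make_grid(prior, n_nodes, bounds)
    ll = log_likelihood(pat, bank, grid.nodes)
    mean, sd = _posterior_moments(ll, grid)
    return ScoreEstimate(mean, sd, "EAP", len(pat))


# ---------------------------------------------------------------------------
# Sum-score EAP (Lord-Wingersky recursion)

def _resolve_item_set(
    item_set: str | Sequence[str] | None, bank: MetricBank
) -> tuple[str, tuple[ItemParameters, ...]]:
    """Accept an instrument label, a sequence of codes, or None (whole bank)."""
    if item_set is None:
        return bank.name, bank.items
    if isinstance(item_set, str):
        return item_set, bank.instrument_items(item_set)
    items = tuple(bank.item(c) for c in item_set)
    if not items:
        raise ValueError("empty item set")
    return ",".join(it.code for it in items), items


def _score_distribution(
    items: Sequence[ItemParameters], nodes: np.ndarray, D: float
) -> np.ndarray:
    """P(total score = s | theta) for every node: shape (max_score+1, n_nodes).

    Lord-Wingersky recursion: fold items in one at a time, convolving the
    running total-score distribution with each item's category
    probabilities.
    """
    nodes = np.asarray(nodes, dtype=float)
    f = np.ones((1, nodes.size))
    for item in items:
        p = category_probs(item, nodes, D)  # (n_nodes, K)
        K = item.n_categories
        g = np.zeros((f.shape[0] + K - 1, nodes.size))
        for k in range(K):
            g[k:k + f.shape[0]] += f * p[:, k]
        f = g
    return f


def sumscore_table(
    item_set: str | Sequence[str] | None,
    bank: MetricBank,
    prior: Prior | None = None,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> pd.DataFrame:
    """EAP estimate and SE for every possible total score of an item set.

    Returns a DataFrame with columns ``sum_score``, ``theta``, ``se`` —
    the package's equivalent of a sum-score conversion table.
    """
    prior = prior or Prior.standard()
    _, items = _resolve_item_set(item_set, bank)
    grid = make_grid(prior, n_nodes, bounds)
    dist = _score_distribution(items, grid.nodes, bank.scaling_D)
    rows = []
    for s in range(dist.shape[0]):
        with np.errstate(divide="ignore"):
            ll = np.log(np.clip(dist[s], PROB_FLOOR, None))
        mean, sd = _posterior_moments(ll, grid)
        rows.append((s, mean, sd))
    return pd.DataFrame(rows, columns=["sum_score", "theta", "se"])


def estimate_eap_sumscore(
    sum_score: int,
    item_set: str | Sequence[str] | None,
    bank: MetricBank,
    prior: Prior | None = None,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> ScoreEstimate:
    """EAP estimate from a total raw score over a complete item set."""
    _, items = _resolve_item_set(item_set, bank)
    max_score = sum(it.max_category for it in items)
    if not 0 <= sum_score <= max_score:
        raise ValueError(
            f"sum score {sum_score} outside [0, {max_score}] for this item set")
    table = sumscore_table(item_set, bank, prior, n_nodes, bounds)
    row = table.iloc[int(sum_score)]
    return ScoreEstimate(float(row["theta"]), float(row["se"]),
                         "EAPsum", len(items))


# ---------------------------------------------------------------------------
# Root finding (MAP / ML / WLE)

def _find_root(
    f: Callable[[float], float],
    fprime: Callable[[float], float] | None,
    lo: float,
    hi: float,
    x0: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, str]:
    """Root of a decreasing-through-zero function on [lo, hi].

    Safeguarded Newton: a sign-change bracket is maintained and any
    Newton step leaving it falls back to bisection.  Returns
    ``(x, status)`` with status ``interior``, ``at_lo`` or ``at_hi``
    (the latter two when f has no sign change on the interval).
    """
    flo, fhi = f(lo), f(hi)
    if flo <= 0.0:
        return (lo, "interior") if flo == 0.0 else (lo, "at_lo")
    if fhi >= 0.0:
        return (hi, "interior") if fhi == 0.0 else (hi, "at_hi")
    a, b = lo, hi
    x = min(max(x0, a), b)
    for _ in range(max_iter):
        fx = f(x)
        if fx > 0.0:
            a = x
        elif fx < 0.0:
            b = x
        else:
            return x, "interior"
        step_ok = False
        if fprime is not None:
            d = fprime(x)
            if np.isfinite(d) and d < 0.0:
                x_new = x - fx / d
                if a < x_new < b:
                    step_ok = True
        if not step_ok:
            x_new = 0.5 * (a + b)
        if abs(x_new - x) < tol:
            return x_new, "interior"
        x = x_new
    return x, "interior"


def _answered_items(
    pattern: Mapping[str, int], bank: MetricBank
) -> tuple[dict[str, int], tuple[ItemParameters, ...]]:
    pat = _as_pattern(pattern)
    return pat, tuple(bank.item(c) for c in pat)


def estimate_map(
    pattern: Mapping[str, int],
    bank: MetricBank,
    prior: Prior | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-6,
) -> ScoreEstimate:
    """Bayes modal (MAP) estimate: mode of the posterior under a normal prior.

    SE is the inverse square root of minus the log-posterior curvature at
    the mode.
    """
    prior = prior or Prior.standard()
    pat = _as_pattern(pattern)
    if not pat:
        return ScoreEstimate(prior.mean, prior.sd, "MAP", 0,
                             frozenset({ALL_MISSING}))

    def grad(th: float) -> float:
        g, _ = score_function(pat, bank, th)
        return float(g) - (th - prior.mean) / prior.variance

    def hess(th: float) -> float:
        _, h = score_function(pat, bank, th)
        return float(h) - 1.0 / prior.variance

    x, status = _find_root(grad, hess, bounds[0], bounds[1], prior.mean, tol)
    flags = frozenset() if status == "interior" else frozenset({AT_BOUND})
    curv = -hess(x)
    se = 1.0 / math.sqrt(curv) if curv > 0 else math.nan
    return ScoreEstimate(x, se, "MAP", len(pat), flags)


def _is_structurally_divergent(
    pat: Mapping[str, int], items: Sequence[ItemParameters]
) -> bool:
    """All answered responses in the lowest or all in the highest category."""
    cats = [pat[it.code] for it in items]
    if all(c == 0 for c in cats):
        return True
    return all(c == it.max_category for c, it in zip(cats, items))


def estimate_ml(
    pattern: Mapping[str, int],
    bank: MetricBank,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-6,
) -> ScoreEstimate:
    """Maximum-likelihood estimate; SE from Fisher information at the MLE.

    All-lowest or all-highest patterns have a likelihood that increases
    without bound toward -inf/+inf: they are flagged ``DIVERGED`` and both
    estimate and SE are missing.  A bounded optimum with nonzero gradient
    at the search bound is flagged ``AT_BOUND``.
    """
    pat, items = _answered_items(pattern, bank)
    if not pat:
        return ScoreEstimate(math.nan, math.nan, "ML", 0,
                             frozenset({ALL_MISSING}))
    if _is_structurally_divergent(pat, items):
        return ScoreEstimate(math.nan, math.nan, "ML", len(pat),
                             frozenset({DIVERGED}))

    def grad(th: float) -> float:
        g, _ = score_function(pat, bank, th)
        return float(g)

    def hess(th: float) -> float:
        _, h = score_function(pat, bank, th)
        return float(h)

    x, status = _find_root(grad, hess, bounds[0], bounds[1], 0.0, tol)
    flags = frozenset() if status == "interior" else frozenset({AT_BOUND})
    info = float(test_information(items, x, bank.scaling_D))
    se = 1.0 / math.sqrt(info) if info > 0 else math.nan
    return ScoreEstimate(x, se, "ML", len(pat), flags)


def estimate_wle(
    pattern: Mapping[str, int],
    bank: MetricBank,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-6,
) -> ScoreEstimate:
    """Warm's weighted likelihood estimate.

    Solves ``score(theta) + J(theta) / (2 I(theta)) = 0`` where I is the
    test information of the answered items and J the companion sum of
    ``P' P'' / P`` over items and categories.  The correction keeps the
    estimate finite for all-extreme patterns where ML diverges, and
    removes the leading-order ML bias.  SE = 1/sqrt(I) at the estimate.
    """
    pat, items = _answered_items(pattern, bank)
    if not pat:
        return ScoreEstimate(math.nan, math.nan, "WLE", 0,
                             frozenset({ALL_MISSING}))
    D = bank.scaling_D

    def _parts(th: float) -> tuple[float, float]:
        """Weighted score and an inexpensive slope for the Newton step.

        One derivative evaluation per item yields the score g, the
        log-likelihood curvature h, the test information I and the
        companion J simultaneously.  h is used as the Newton slope: near
        the root it is dominated by -I, and the bracket safeguard in the
        root finder covers the neglected derivative of the correction.
        """
        g = h = info = comp = 0.0
        for it in items:
            p, dp, d2p = category_prob_derivs(it, th, D)
            psafe = np.clip(p, PROB_FLOOR, None)
            cat = pat[it.code]
            r = dp[cat] / psafe[cat]
            g += r
            h += d2p[cat] / psafe[cat] - r * r
            info += float(np.sum(dp * dp / psafe))
            comp += float(np.sum(dp * d2p / psafe))
        return g + comp / (2.0 * max(info, PROB_FLOOR)), h

    cache: dict[float, tuple[float, float]] = {}

    def weighted_score(th: float) -> float:
        val = _parts(th)
        cache.clear()
        cache[th] = val
        return val[0]

    def wprime(th: float) -> float:
        val = cache.get(th)
        if val is None:
            val = _parts(th)
        return val[1]

    # The weighted score can have several roots (GPCM items with
    # unordered steps).  Treat its antiderivative as the objective:
    # scan a coarse grid, and refine the downward crossing with the
    # largest integrated value (the global weighted-likelihood maximum).
    grid = np.linspace(bounds[0], bounds[1], 241)
    gv = np.zeros(grid.size)
    infov = np.zeros(grid.size)
    compv = np.zeros(grid.size)
    for it in items:
        p, dp, d2p = category_prob_derivs(it, grid, D)
        psafe = np.clip(p, PROB_FLOOR, None)
        cat = pat[it.code]
        gv += dp[:, cat] / psafe[:, cat]
        infov += np.sum(dp * dp / psafe, axis=1)
        compv += np.sum(dp * d2p / psafe, axis=1)
    fv = gv + compv / (2.0 * np.clip(infov, PROB_FLOOR, None))
    down = np.where((fv[:-1] > 0) & (fv[1:] <= 0))[0]
    if down.size >= 1:
        step = grid[1] - grid[0]
        cumW = np.concatenate(
            [[0.0], np.cumsum(0.5 * (fv[:-1] + fv[1:]) * step)])
        i = int(down[np.argmax(cumW[down])])
        x, status = _find_root(weighted_score, wprime, grid[i], grid[i + 1],
                               0.5 * (grid[i] + grid[i + 1]), tol)
    else:
        x, status = _find_root(weighted_score, wprime, bounds[0], bounds[1],
                               0.0, tol)
    flags = frozenset() if status == "interior" else frozenset({AT_BOUND})
    info = float(test_information(items, x, D))
    se = 1.0 / math.sqrt(info) if info > 0 else math.nan
    return ScoreEstimate(x, se, "WLE", len(pat), flags)


# ---------------------------------------------------------------------------
# Empirical prior (EM with fixed item parameters)

def estimate_prior_from_data(
    responses: ResponseMatrix,
    bank: MetricBank,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-4,
    max_iter: int = 100,
    min_rows: int = 50,
    init: tuple[float, float] = (0.0, 1.0),
) -> Prior:
    """Estimate a normal prior's mean and variance from the sample.

    Marginal maximum likelihood with all item parameters fixed: EM on the
    quadrature grid, where the E-step computes each respondent's posterior
    node weights under the current prior and the M-step sets the prior
    mean and variance to the posterior-weighted sample moments.  Stops
    when both parameters move less than ``tol`` or after ``max_iter``
    iterations.

    Fewer than ``min_rows`` usable rows triggers a warning and a fallback
    to the standard N(0,1) prior; a table with no answered responses at
    all is an error.
    """
    answered = (responses.data != MISSING).any(axis=1)
    n_used = int(answered.sum())
    if n_used == 0:
        raise ValueError("cannot estimate a prior: all rows are empty")
    if n_used < min_rows:
        warnings.warn(
            f"only {n_used} rows with any responses (< {min_rows}); "
            "falling back to the standard N(0,1) prior", UserWarning)
        return Prior.standard()

    nodes = np.linspace(bounds[0], bounds[1], n_nodes)
    sub = ResponseMatrix(responses.codes, responses.data[answered])
    ll = pattern_loglik_matrix(sub, bank, nodes)  # (n_used, n_nodes)
    mean, var = float(init[0]), float(init[1])
    for _ in range(max_iter):
        logw = (-0.5 * (nodes - mean) ** 2 / var)
        logpost = ll + logw
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        new_mean = float(np.mean(post @ nodes))
        new_var = float(np.mean(post @ (nodes ** 2)) - new_mean ** 2)
        new_var = max(new_var, 1e-6)
        done = abs(new_mean - mean) < tol and abs(new_var - var) < tol
        mean, var = new_mean, new_var
        if done:
            break
    return Prior.empirical(mean, var)


# ---------------------------------------------------------------------------
# Table-level scoring

def _normalize_estimator(name: str) -> str:
    key = name.replace("-", "").replace("_", "").lower()
    table = {"eap": "EAP", "eapsum": "EAPsum", "map": "MAP",
             "wle": "WLE", "ml": "ML"}
    if key not in table:
        raise ValueError(
            f"unknown estimator {name!r}; choose from {ESTIMATORS}")
    return table[key]


def score_table(
    responses: ResponseMatrix,
    bank: MetricBank,
    estimator: str = "EAP",
    prior: Prior | None = None,
    instrument: str | None = None,
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> list[ScoreEstimate]:
    """Score every row of a response matrix; row order is preserved.

    The default is the application's default: pattern EAP with the
    standard N(0,1) prior.  For ``EAPsum`` the relevant instrument must
    be named (or the bank must hold a single instrument); rows that have
    not answered every item of that instrument are flagged
    ``INCOMPLETE_FOR_SUMSCORE`` with a missing estimate.  ``WLE`` and
    ``ML`` use no prior; a supplied prior is ignored with a logged
    notice.
    """
    est = _normalize_estimator(estimator)
    if est in ("WLE", "ML"):
        if prior is not None:
            logger.info("%s estimation uses no prior; the supplied prior "
                        "is ignored", est)
        prior = None
    else:
        prior = prior or Prior.standard()

    out: list[ScoreEstimate] = []
    if est == "EAP":
        grid = make_grid(prior, n_nodes, bounds)
        ll = pattern_loglik_matrix(responses, bank, grid.nodes)
        n_ans = (responses.data != MISSING).sum(axis=1)
        for i in range(responses.n_rows):
            if n_ans[i] == 0:
                out.append(ScoreEstimate(prior.mean, prior.sd, "EAP", 0,
                                         frozenset({ALL_MISSING})))
            else:
                mean, sd = _posterior_moments(ll[i], grid)
                out.append(ScoreEstimate(mean, sd, "EAP", int(n_ans[i])))
        return out

    if est == "EAPsum":
        if instrument is None:
            groups = bank.instruments
            if len(groups) == 1:
                instrument = next(iter(groups))
            else:
                raise ValueError(
                    "EAPsum needs an instrument label; available: "
                    f"{sorted(groups)}")
        items = bank.instrument_items(instrument)
        codes = [it.code for it in items]
        table = sumscore_table(instrument, bank, prior, n_nodes, bounds)
        idx = [responses.codes.index(c) if c in responses.codes else None
               for c in codes]
        for i in range(responses.n_rows):
            cats = [responses.data[i, j] if j is not None else MISSING
                    for j in idx]
            if any(c == MISSING for c in cats):
                n_ans = sum(c != MISSING for c in cats)
                out.append(ScoreEstimate(
                    math.nan, math.nan, "EAPsum", n_ans,
                    frozenset({INCOMPLETE_FOR_SUMSCORE})))
            else:
                row = table.iloc[int(sum(cats))]
                out.append(ScoreEstimate(float(row["theta"]),
                                         float(row["se"]),
                                         "EAPsum", len(cats)))
        return out

    fn = {"MAP": lambda p: estimate_map(p, bank, prior, bounds),
          "WLE": lambda p: estimate_wle(p, bank, bounds),
          "ML": lambda p: estimate_ml(p, bank, bounds)}[est]
    for i in range(responses.n_rows):
        out.append(fn(responses.row_pattern(i)))
    return out
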