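"""Category probabilities, derivatives, likelihood and information.

Both models are logistic polytomous IRT models with all item parameters
fixed.  For an item with discrimination a, K categories and theta the
latent variable:

*Graded response model (GRM).*  Cumulative boundary probabilities
``P*_k(theta) = logistic(D a (theta - b_k))`` for k = 1..K-1, with
``P*_0 = 1`` and ``P*_K = 0``; category probabilities are the differences
``P_k = P*_k - P*_{k+1}``.  The b_k are strictly increasing.

*Generalized partial credit model (GPCM).*
``P_k(theta) ∝ exp( sum_{j<=k} D a (theta - d_j) )`` with the empty sum
equal to 0 for k = 0, normalized over categories.  The step parameters
d_j need not be ordered.

D is a bank-level scaling constant (default 1.0; set 1.7 for parameter
sets published on the normal-ogive-approximating scale).

All functions broadcast over theta: pass a scalar or an ndarray and the
category axis is appended last.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, log_softmax, softmax

from .bank import GPCM, GRM, MISSING, ItemParameters, MetricBank

__all__ = [
    "grm_category_probs", "gpcm_category_probs", "category_probs",
    "category_prob_derivs", "log_category_probs", "log_likelihood",
    "score_function", "item_information", "item_information_companion",
    "test_information",
]

#: Probability floor applied before logs/divisions; extreme theta with
#: steep slopes otherwise underflows to exactly 0.
PROB_FLOOR = 1e-300


def _check_model(item: ItemParameters, model: str) -> None:
    if item.model != model:
        raise ValueError(f"item {item.code!r} is {item.model}, not {model}")


def grm_category_probs(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """GRM category probabilities, shape ``theta.shape + (K,)``."""
    _check_model(item, GRM)
    th = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds)
    # boundary curves with the fixed outer boundaries 1 and 0
    pstar = expit(D * item.a * (th[..., None] - b))
    ones = np.ones(th.shape + (1,))
    zeros = np.zeros(th.shape + (1,))
    cum = np.concatenate([ones, pstar, zeros], axis=-1)
    p = cum[..., :-1] - cum[..., 1:]
    return np.clip(p, 0.0, 1.0)


def gpcm_category_probs(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """GPCM category probabilities, shape ``theta.shape + (K,)``."""
    _check_model(item, GPCM)
    th = np.asarray(theta, dtype=float)
    d = np.asarray(item.thresholds)
    steps = D * item.a * (th[..., None] - d)
    zeros = np.zeros(th.shape + (1,))
    # cumulative numerator exponents s_k = sum_{j<=k} Da(theta - d_j), s_0 = 0
    s = np.concatenate([zeros, np.cumsum(steps, axis=-1)], axis=-1)
    return softmax(s, axis=-1)


def category_probs(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Dispatch on the item's model family."""
    if item.model == GRM:
        return grm_category_probs(item, theta, D)
    return gpcm_category_probs(item, theta, D)


def log_category_probs(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """log P_k(theta); floored at log(PROB_FLOOR) for the GRM differences."""
    if item.model == GPCM:
        th = np.asarray(theta, dtype=float)
        d = np.asarray(item.thresholds)
        steps = D * item.a * (th[..., None] - d)
        zeros = np.zeros(th.shape + (1,))
        s = np.concatenate([zeros, np.cumsum(steps, axis=-1)], axis=-1)
        return log_softmax(s, axis=-1)
    p = grm_category_probs(item, theta, D)
    return np.log(np.clip(p, PROB_FLOOR, None))


def category_prob_derivs(
    item: ItemParameters, theta, D: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P, dP/dtheta, d2P/dtheta2), each of shape ``theta.shape + (K,)``.

    Derivatives are analytic: for the GRM they follow from the logistic
    boundary curves (``dP* = Da P*(1-P*)``); for the GPCM from the
    exponential-family identities ``dP_k = Da P_k (k - E[X])`` and
    ``d2P_k = (Da)^2 P_k ((k - E[X])^2 - Var[X])``.
    """
    th = np.asarray(theta, dtype=float)
    Da = D * item.a
    if item.model == GRM:
        b = np.asarray(item.thresholds)
        pstar = expit(Da * (th[..., None] - b))
        ones = np.ones(th.shape + (1,))
        zeros = np.zeros(th.shape + (1,))
        cum = np.concatenate([ones, pstar, zeros], axis=-1)
        dcum = Da * cum * (1.0 - cum)          # zero at the fixed boundaries
        d2cum = Da * dcum * (1.0 - 2.0 * cum)
        p = np.clip(cum[..., :-1] - cum[..., 1:], 0.0, 1.0)
        dp = dcum[..., :-1] - dcum[..., 1:]
        d2p = d2cum[..., :-1] - d2cum[..., 1:]
        return p, dp, d2p
    p = gpcm_category_probs(item, theta, D)
    k = np.arange(item.n_categories, dtype=float)
    mean = np.sum(k * p, axis=-1, keepdims=True)
    var = np.sum((k - mean) ** 2 * p, axis=-1, keepdims=True)
    dev = k - mean
    dp = Da * p * dev
    d2p = Da * Da * p * (dev ** 2 - var)
    return p, dp, d2p


def item_information(item: ItemParameters, theta, D: float = 1.0) -> np.ndarray:
    """Fisher (expected) item information ``sum_k (P'_k)^2 / P_k``; >= 0."""
    p, dp, _ = category_prob_derivs(item, theta, D)
    return np.sum(dp * dp / np.clip(p, PROB_FLOOR, None), axis=-1)


def item_information_companion(
    item: ItemParameters, theta, D: float = 1.0
) -> np.ndarray:
    """The companion sum ``J = sum_k P'_k P''_k / P_k`` used by Warm's WLE."""
    p, dp, d2p = category_prob_derivs(item, theta, D)
    return np.sum(dp * d2p / np.clip(p, PROB_FLOOR, None), axis=-1)


def test_information(
    items: Sequence[ItemParameters] | MetricBank, theta, D: float | None = None
) -> np.ndarray:
    """Total Fisher information of an item set: the sum over items.

    ``items`` may be a MetricBank (its scaling_D is used unless ``D`` is
    given) or any nonempty sequence of items.
    """
    if isinstance(items, MetricBank):
        if D is None:
            D = items.scaling_D
        items = items.items
    if D is None:
        D = 1.0
    items = list(items)
    if not items:
        raise ValueError("test_information requires a nonempty item set")
    th = np.asarray(theta, dtype=float)
    total = np.zeros(th.shape)
    for it in items:
        total = total + item_information(it, th, D)
    return total


def log_likelihood(
    pattern: Mapping[str, int], bank: MetricBank, theta
) -> np.ndarray:
    """Log-likelihood of one response pattern at theta.

    ``pattern`` maps item codes to internal categories; items missing from
    the mapping (or mapped to MISSING) contribute nothing, so scoring is
    tolerant of missing responses by construction.  An empty pattern has
    log-likelihood 0 for every theta.
    """
    th = np.asarray(theta, dtype=float)
    total = np.zeros(th.shape)
    for code, cat in pattern.items():
        if cat == MISSING:
            continue
        item = bank.item(code)
        if not (0 <= cat < item.n_categories):
            raise ValueError(
                f"category {cat} out of range for item {code!r} "
                f"(K={item.n_categories})")
        total = total + log_category_probs(item, th, bank.scaling_D)[..., cat]
    return total


def score_function(
    pattern: Mapping[str, int], bank: MetricBank, theta
) -> tuple[np.ndarray, np.ndarray]:
    """(d/dtheta log L, d2/dtheta2 log L) of a pattern, both analytic."""
    th = np.asarray(theta, dtype=float)
    g = np.zeros(th.shape)
    h = np.zeros(th.shape)
    for code, cat in pattern.items():
        if cat == MISSING:
            continue
        item = bank.item(code)
        p, dp, d2p = category_prob_derivs(item, th, bank.scaling_D)
        pk = np.clip(p[..., cat], PROB_FLOOR, None)
        r = dp[..., cat] / pk
        g = g + r
        h = h + d2p[..., cat] / pk - r * r
    return g, h
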