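"""T-metric transformation, descriptive statistics, precision curves.

Theta estimates and their standard errors are reported on the T metric,
the linear scale with mean 50 and SD 10 anchored to the calibration
population: ``t = 50 + 10 theta`` and ``se_t = 10 se``.  For the real
common metrics T = 50 typically marks the general-population mean.

Precision curves show the standard error of measurement
``SE(theta) = 1 / sqrt(I(theta))`` over the latent continuum for an item
set — the whole metric or one legacy instrument — in T-metric units.
These curves are valid under ML estimation only, and every curve object
carries that annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bank import MetricBank, ResponseMatrix
from .estimation import DEFAULT_BOUNDS, DEFAULT_NODES, ScoreEstimate
from .models import test_information

__all__ = [
    "T_MEAN", "T_SD", "PRECISION_VALIDITY_NOTE",
    "TScore", "SummaryStats", "PrecisionCurve",
    "to_t_metric", "from_t_metric", "summarize", "precision_curves",
    "precision_frame", "scored_frame",
]

T_MEAN = 50.0
T_SD = 10.0

PRECISION_VALIDITY_NOTE = "valid under ML estimation only"


@dataclass(frozen=True)
class TScore:
    """An estimate on the T metric; NaN propagates from missing estimates."""

    t: float
    se_t: float


def to_t_metric(estimate: ScoreEstimate | float) -> TScore:
    """Transform a theta estimate (and SE) to the T metric."""
    if isinstance(estimate, ScoreEstimate):
        return TScore(T_MEAN + T_SD * estimate.theta_hat,
                      T_SD * estimate.se)
    return TScore(T_MEAN + T_SD * float(estimate), math.nan)


def from_t_metric(t: float) -> float:
    """Inverse transform: T score back to theta."""
    return (t - T_MEAN) / T_SD


@dataclass(frozen=True)
class SummaryStats:
    """Descriptives of a scored table, computed over non-missing T scores."""

    n: int
    min: float
    mean: float
    median: float
    max: float
    sd: float
    sem: float
    pct_missing: float
    histogram_bin_edges: tuple[float, ...] = ()


def _fd_bin_edges(values: np.ndarray, min_bins: int = 5) -> np.ndarray:
    """Freedman-Diaconis histogram edges with a floor on the bin count."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.linspace(lo - 0.5, hi + 0.5, min_bins + 1)
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    n = values.size
    width = 2.0 * iqr / n ** (1.0 / 3.0)
    n_bins = min_bins if width <= 0 else max(min_bins,
                                             int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi, n_bins + 1)


def summarize(tscores: Sequence[TScore]) -> SummaryStats:
    """n, min, mean, median, max, SD, SEM and % missing of T scores.

    Mirrors the descriptive panel of the estimates view: missing
    (flagged) estimates enter only the missing percentage.  With a single
    usable score the SD and SEM are undefined (NaN).
    """
    if not tscores:
        raise ValueError("summarize needs at least one estimate")
    vals = np.array([ts.t for ts in tscores], dtype=float)
    ok = np.isfinite(vals)
    n_total = vals.size
    pct_missing = 100.0 * (n_total - ok.sum()) / n_total
    if not ok.any():
        nan = math.nan
        return SummaryStats(0, nan, nan, nan, nan, nan, nan, 100.0)
    v = vals[ok]
    sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
    sem = sd / math.sqrt(v.size) if v.size > 1 else math.nan
    return SummaryStats(
        n=int(v.size),
        min=float(v.min()),
        mean=float(v.mean()),
        median=float(np.median(v)),
        max=float(v.max()),
        sd=sd,
        sem=sem,
        pct_missing=pct_missing,
        histogram_bin_edges=tuple(_fd_bin_edges(v)),
    )


@dataclass(frozen=True)
class PrecisionCurve:
    """SE of measurement over the theta grid for one item set, in T units."""

    item_set_label: str
    grid: np.ndarray
    se_values: np.ndarray
    note: str = PRECISION_VALIDITY_NOTE


def precision_curves(
    bank: MetricBank,
    item_sets: Sequence[str] = ("ALL",),
    n_nodes: int = DEFAULT_NODES,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> list[PrecisionCurve]:
    """SE-of-measurement curves for the whole metric and/or instruments.

    ``item_sets`` contains instrument labels and/or the pseudo-label
    ``"ALL"`` for the whole bank.  All curves share one grid so they can
    be compared pointwise.  Unknown labels raise a KeyError listing the
    available instruments.
    """
    grid = np.linspace(bounds[0], bounds[1], n_nodes)
    available = bank.instruments
    curves = []
    for label in item_sets:
        if label == "ALL":
            items = bank.items
            shown = bank.name or "ALL"
        elif label in available:
            items = bank.instrument_items(label)
            shown = label
        else:
            raise KeyError(
                f"unknown instrument {label!r}; available: "
                f"{sorted(available)} (or 'ALL')")
        info = test_information(items, grid, bank.scaling_D)
        se = T_SD / np.sqrt(info)
        curves.append(PrecisionCurve(shown, grid, se))
    return curves


def precision_frame(curves: Sequence[PrecisionCurve]) -> pd.DataFrame:
    """Tabular form: one theta column plus one SE column per item set."""
    if not curves:
        raise ValueError("no curves")
    data = {"theta": curves[0].grid}
    for c in curves:
        data[f"se_t[{c.item_set_label}]"] = c.se_values
    return pd.DataFrame(data)


def scored_frame(
    input_table: pd.DataFrame,
    estimates: Sequence[ScoreEstimate],
    estimator: str,
    round_decimals: int | None = None,
) -> pd.DataFrame:
    """Input columns preserved, score columns appended.

    Appends ``theta_<estimator>``, ``se_theta``, ``tscore``,
    ``se_tscore``, ``n_items_answered`` and ``flags`` — the downloadable
    dataset of the scoring workflow.  ``round_decimals`` optionally
    rounds the numeric score columns for CSV export.
    """
    if len(input_table) != len(estimates):
        raise ValueError("one estimate per input row required")
    out = input_table.copy()
    theta = np.array([e.theta_hat for e in estimates])
    se = np.array([e.se for e in estimates])
    out[f"theta_{estimator}"] = theta
    out["se_theta"] = se
    out["tscore"] = T_MEAN + T_SD * theta
    out["se_tscore"] = T_SD * se
    out["n_items_answered"] = [e.n_items_answered for e in estimates]
    out["flags"] = ["|".join(sorted(e.flags)) for e in estimates]
    if round_decimals is not None:
        for col in (f"theta_{estimator}", "se_theta", "tscore", "se_tscore"):
            out[col] = out[col].round(round_decimals)
    return out
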