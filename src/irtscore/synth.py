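"""Synthetic item banks and simulated response data.

The published item parameters of the real depression/anxiety/physical-
function metrics live in their source publications and are not shipped
here; this module generates realistic stand-in banks and response data so
every estimator, report and test runs without any download.

The default example bank mimics the shape of a two-instrument depression
metric: a 9-item and a 7-item questionnaire (PHQ-9 / GAD-7 scale sizes),
all items with four response categories, graded response model.
Discriminations are drawn uniformly from a range typical of published
PRO calibrations; GRM thresholds are sorted uniform draws.

Respondents are simulated by drawing theta from a normal population
distribution and sampling each item response from the model's category
probabilities at that theta, with optional missing-completely-at-random
(MCAR) missingness.  True theta values are returned separately — they
are never written into the response table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import GRM, MISSING, ItemParameters, MetricBank, ResponseMatrix

__all__ = ["BankRecipe", "SimulationConfig", "make_example_bank",
           "simulate_responses", "simulated_matrix"]


@dataclass(frozen=True)
class BankRecipe:
    """Recipe for a generated bank.

    ``instruments`` maps instrument label -> (n_items, n_categories).
    Slopes are uniform in ``slope_range``; thresholds/steps are uniform
    draws in ``threshold_range`` (sorted for the GRM).
    """

    instruments: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"instrA": (9, 4), "instrB": (7, 4)})
    model: str = GRM
    slope_range: tuple[float, float] = (0.8, 2.5)
    threshold_range: tuple[float, float] = (-2.5, 2.5)
    name: str = "example metric"

    def __post_init__(self) -> None:
        lo, hi = self.slope_range
        if not (0 < lo <= hi):
            raise ValueError("slope range must be positive")
        for label, (n, k) in self.instruments.items():
            if n < 1 or k < 2:
                raise ValueError(
                    f"instrument {label!r}: need n_items >= 1, K >= 2")


@dataclass(frozen=True)
class SimulationConfig:
    """Population and sampling settings for simulated respondents."""

    n_respondents: int = 100
    theta_mean: float = 0.0
    theta_var: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (self.theta_var > 0):
            raise ValueError("theta_var must be > 0")


def make_example_bank(
    recipe: BankRecipe | None = None, seed: int = 0
) -> MetricBank:
    """Generate a reproducible multi-instrument bank from a recipe.

    The same seed always yields an identical bank.  Raw response codes
    are ``0..K-1`` (as printed on most PRO instruments).
    """
    recipe = recipe or BankRecipe()
    rng = np.random.default_rng(seed)
    items = []
    for label, (n_items, k) in recipe.instruments.items():
        for i in range(n_items):
            a = float(rng.uniform(*recipe.slope_range))
            thr = rng.uniform(*recipe.threshold_range, size=k - 1)
            if recipe.model == GRM:
                thr = np.sort(thr)
                # degenerate ties are measure-zero but guard anyway
                while np.any(np.diff(thr) <= 0):
                    thr = np.sort(
                        rng.uniform(*recipe.threshold_range, size=k - 1))
            items.append(ItemParameters(
                code=f"{label}_{i + 1:02d}",
                model=recipe.model,
                a=a,
                thresholds=tuple(float(t) for t in thr),
                raw_codes=tuple(str(c) for c in range(k)),
                instrument=label,
            ))
    return MetricBank(
        name=recipe.name,
        model=recipe.model,
        items=tuple(items),
        anchor_note="T=50 is the mean of the simulated reference population",
        provenance="synthetic bank generated by irtscore.synth",
    )


def simulate_responses(
    bank: MetricBank,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a raw response table and its true theta vector.

    Returns ``(table, theta)``: the table holds raw response codes as
    strings with empty cells for missing values, ready to be written as
    CSV and ingested back; ``theta`` holds the generating latent values
    (kept separate from the table by design).
    """
    from .models import category_probs

    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    theta = rng.normal(config.theta_mean, np.sqrt(config.theta_var), size=n)
    columns: dict[str, list[str]] = {}
    for item in bank.items:
        probs = category_probs(item, theta, bank.scaling_D)  # (n, K)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        cats = (u[:, None] > cum).sum(axis=1)
        cells = [item.raw_codes[c] for c in cats]
        if config.missing_rate > 0:
            drop = rng.random(n) < config.missing_rate
            cells = ["" if d else c for c, d in zip(cells, drop)]
        columns[item.code] = cells
    return pd.DataFrame(columns), theta


def simulated_matrix(
    bank: MetricBank, config: SimulationConfig
) -> tuple[ResponseMatrix, np.ndarray]:
    """Convenience: simulate and ingest in one step."""
    from .bank import ingest_responses

    table, theta = simulate_responses(bank, config)
    rm, _ = ingest_responses(table, bank)
    return rm, theta
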