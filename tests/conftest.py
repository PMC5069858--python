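import numpy as np
import pytest

from irtscore import (
    BankRecipe,
    ItemParameters,
    MetricBank,
    SimulationConfig,
    make_example_bank,
)
from irtscore.synth import simulated_matrix


def grm_item(code="g1", a=1.0, thresholds=(0.0,), instrument="toy"):
    return ItemParameters(code=code, model="GRM", a=a,
                          thresholds=tuple(thresholds),
                          raw_codes=tuple(str(i) for i in
                                          range(len(thresholds) + 1)),
                          instrument=instrument)


def gpcm_item(code="p1", a=1.0, steps=(0.0,), instrument="toy"):
    return ItemParameters(code=code, model="GPCM", a=a,
                          thresholds=tuple(steps),
                          raw_codes=tuple(str(i) for i in
                                          range(len(steps) + 1)),
                          instrument=instrument)


def random_bank(rng, model="GRM", n_items=None, max_items=10, max_k=5):
    """A small random bank for oracle-equivalence checks."""
    n_items = n_items or int(rng.integers(2, max_items + 1))
    items = []
    for i in range(n_items):
        k = int(rng.integers(2, max_k + 1))
        a = float(rng.uniform(0.5, 2.5))
        thr = np.sort(rng.uniform(-2.5, 2.5, size=k - 1))
        if model == "GRM":
            while np.any(np.diff(thr) <= 0):
                thr = np.sort(rng.uniform(-2.5, 2.5, size=k - 1))
        else:
            thr = rng.uniform(-2.5, 2.5, size=k - 1)  # unordered is legal
        items.append(ItemParameters(
            code=f"it{i:02d}", model=model, a=a,
            thresholds=tuple(float(t) for t in thr),
            raw_codes=tuple(str(c) for c in range(k)),
            instrument="rand"))
    return MetricBank(name="random toy bank", model=model,
                      items=tuple(items))


def random_pattern(rng, bank, interior=False):
    """One response per item; `interior` avoids all-extreme patterns."""
    pat = {}
    for it in bank.items:
        pat[it.code] = int(rng.integers(0, it.n_categories))
    if interior:
        cats = list(pat.values())
        maxes = [it.max_category for it in bank.items]
        if all(c == 0 for c in cats) or \
                all(c == m for c, m in zip(cats, maxes)):
            mid_code = bank.items[0].code
            pat[mid_code] = max(1, bank.items[0].max_category // 2)
    return pat


@pytest.fixture(scope="session")
def example_bank():
    """The default 9 + 7 item two-instrument GRM bank (seeded)."""
    return make_example_bank(seed=20160)


@pytest.fixture(scope="session")
def small_bank():
    """Three mixed-K GRM items; cheap enough for exhaustive checks."""
    return MetricBank(
        name="small", model="GRM",
        items=(grm_item("s1", a=1.2, thresholds=(-1.0, 0.0, 1.0)),
               grm_item("s2", a=0.8, thresholds=(-0.5, 1.5)),
               grm_item("s3", a=2.0, thresholds=(0.3,))))


@pytest.fixture(scope="session")
def simulated_data(example_bank):
    """200 respondents at theta ~ N(0,1), 10% MCAR missing."""
    cfg = SimulationConfig(n_respondents=200, missing_rate=0.1, seed=7)
    return simulated_matrix(example_bank, cfg)
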