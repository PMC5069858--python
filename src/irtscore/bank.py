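"""Item-parameter banks for common metrics, and response-data ingestion.

A bank is one JSON document per metric::

    {
      "name": ..., "model": "GRM" | "GPCM", "scaling_D": 1.0,
      "anchor_note": ..., "provenance": ...,
      "items": [
        {"code": "phq9_01", "instrument": "PHQ-9", "a": 1.7,
         "thresholds": [-0.5, 0.6, 1.4], "raw_codes": [0, 1, 2, 3]},
        ...
      ]
    }

Item parameters are stored in the discrimination/threshold ("IRT")
parameterization.  ``load_bank(..., parameterization="slope-intercept")``
accepts banks published as slope/intercept pairs (a, c_k) and converts
b_k = -c_k / a on the way in.

Respondent data is a CSV table whose column names are item codes.  Matching
is case-sensitive and exact; any column whose name matches no item code in
the bank is dropped (and reported), mirroring the data-safety rule of the
scoring application this package reimplements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRM", "GPCM", "MISSING",
    "ItemParameters", "MetricBank", "ResponseMatrix", "IngestionReport",
    "BankValidationError",
    "load_bank", "save_bank", "bank_from_dict", "bank_to_dict",
    "ingest_responses",
]

GRM = "GRM"
GPCM = "GPCM"

#: Internal sentinel for a missing response category.
MISSING: int = -1

#: CSV cell values treated as missing (besides the empty cell).
_MISSING_TOKENS = frozenset({"", "NA", "na"})


class BankValidationError(ValueError):
    """Raised when a bank or item violates its structural invariants."""


@dataclass(frozen=True)
class ItemParameters:
    """Fixed parameters of one polytomous item.

    Parameters
    ----------
    code
        Case-sensitive item identifier; must match the data column name.
    model
        ``"GRM"`` (graded response model; `thresholds` are ordered
        category boundaries b_k) or ``"GPCM"`` (generalized partial
        credit model; `thresholds` are step parameters d_k, not
        necessarily ordered).
    a
        Discrimination (logistic slope), strictly positive.
    thresholds
        K-1 location parameters on the latent (theta) scale.
    raw_codes
        The K response codes as printed on the instrument, in the order
        that maps onto internal categories 0..K-1.  Stored as strings for
        exact matching against CSV cells.
    instrument
        Questionnaire the item belongs to.
    """

    code: str
    model: str
    a: float
    thresholds: tuple[float, ...]
    raw_codes: tuple[str, ...]
    instrument: str

    def __post_init__(self) -> None:
        if self.model not in (GRM, GPCM):
            raise BankValidationError(
                f"item {self.code!r}: model must be GRM or GPCM, got {self.model!r}")
        if not (self.a > 0):
            raise BankValidationError(
                f"item {self.code!r}: discrimination a must be > 0, got {self.a}")
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) < 1:
            raise BankValidationError(
                f"item {self.code!r}: needs at least one threshold (K >= 2)")
        if not all(np.isfinite(thr)):
            raise BankValidationError(
                f"item {self.code!r}: thresholds must be finite")
        if self.model == GRM and any(t2 <= t1 for t1, t2 in zip(thr, thr[1:])):
            raise BankValidationError(
                f"item {self.code!r}: GRM thresholds must be strictly "
                f"increasing, got {thr}")
        codes = tuple(str(c) for c in self.raw_codes)
        object.__setattr__(self, "raw_codes", codes)
        if len(codes) != len(thr) + 1:
            raise BankValidationError(
                f"item {self.code!r}: expected {len(thr) + 1} raw codes "
                f"for {len(thr) + 1} categories, got {len(codes)}")
        if len(set(codes)) != len(codes):
            raise BankValidationError(
                f"item {self.code!r}: raw codes must be distinct, got {codes}")

    @property
    def n_categories(self) -> int:
        """Number of response categories K."""
        return len(self.thresholds) + 1

    @property
    def max_category(self) -> int:
        return len(self.thresholds)

    def category_of(self, raw: str) -> int:
        """Internal category (0..K-1) for a raw response code, or MISSING."""
        try:
            return self.raw_codes.index(str(raw))
        except ValueError:
            return MISSING


@dataclass(frozen=True)
class MetricBank:
    """A named common metric: items from several instruments, one model family."""

    name: str
    model: str
    items: tuple[ItemParameters, ...]
    anchor_note: str = ""
    provenance: str = ""
    scaling_D: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in (GRM, GPCM):
            raise BankValidationError(
                f"bank {self.name!r}: model must be GRM or GPCM")
        if not (self.scaling_D > 0):
            raise BankValidationError(
                f"bank {self.name!r}: scaling_D must be > 0")
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise BankValidationError(f"bank {self.name!r}: no items")
        seen: set[str] = set()
        for it in items:
            if it.code in seen:
                raise BankValidationError(
                    f"bank {self.name!r}: duplicate item code {it.code!r}")
            seen.add(it.code)
            if it.model != self.model:
                raise BankValidationError(
                    f"bank {self.name!r}: item {it.code!r} has model "
                    f"{it.model}, bank is {self.model}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(it.code for it in self.items)

    @property
    def instruments(self) -> dict[str, tuple[str, ...]]:
        """Item codes grouped by instrument, in bank order."""
        groups: dict[str, list[str]] = {}
        for it in self.items:
            groups.setdefault(it.instrument, []).append(it.code)
        return {k: tuple(v) for k, v in groups.items()}

    def item(self, code: str) -> ItemParameters:
        for it in self.items:
            if it.code == code:
                return it
        raise KeyError(f"no item {code!r} in bank {self.name!r}")

    def subset(self, codes: Iterable[str], name: str | None = None) -> "MetricBank":
        """A new bank restricted to `codes` (order taken from this bank)."""
        keep = set(codes)
        missing = keep - set(self.codes)
        if missing:
            raise KeyError(f"codes not in bank: {sorted(missing)}")
        return MetricBank(
            name=name or f"{self.name} (subset)",
            model=self.model,
            items=tuple(it for it in self.items if it.code in keep),
            anchor_note=self.anchor_note,
            provenance=self.provenance,
            scaling_D=self.scaling_D,
        )

    def instrument_items(self, label: str) -> tuple[ItemParameters, ...]:
        items = tuple(it for it in self.items if it.instrument == label)
        if not items:
            raise KeyError(
                f"no instrument {label!r} in bank {self.name!r}; "
                f"available: {sorted(self.instruments)}")
        return items


@dataclass(frozen=True)
class IngestionReport:
    """What happened to the raw table on its way into a ResponseMatrix."""

    retained_columns: tuple[str, ...]
    dropped_columns: tuple[str, ...]
    n_rows: int
    n_unmapped_cells: int
    unmapped_by_column: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_input_columns(self) -> int:
        return len(self.retained_columns) + len(self.dropped_columns)


@dataclass(frozen=True)
class ResponseMatrix:
    """Respondent-by-item matrix of internal categories (MISSING = -1).

    ``data`` is an int array of shape (n_respondents, n_items); columns are
    aligned with ``codes``.  Row order is the input row order.
    """

    codes: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != len(self.codes):
            raise ValueError("data shape does not match codes")
        object.__setattr__(self, "data", arr)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def row_pattern(self, i: int) -> dict[str, int]:
        """One row as a {code: category} dict, missing entries omitted."""
        row = self.data[i]
        return {c: int(v) for c, v in zip(self.codes, row) if v != MISSING}

    def to_frame(self) -> pd.DataFrame:
        """Nullable-integer DataFrame view (missing -> <NA>)."""
        df = pd.DataFrame(self.data, columns=list(self.codes)).astype("Int64")
        return df.mask(df == MISSING)


# ---------------------------------------------------------------------------
# JSON (de)serialization

def bank_from_dict(doc: Mapping, *, parameterization: str = "irt") -> MetricBank:
    """Build a MetricBank from a parsed JSON document.

    With ``parameterization="slope-intercept"`` the per-item location
    entries are read as intercepts c_k and converted to thresholds
    b_k = -c_k / a.
    """
    if parameterization not in ("irt", "slope-intercept"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    try:
        model = str(doc["model"]).upper()
        raw_items = doc["items"]
    except KeyError as exc:
        raise BankValidationError(f"bank document missing key {exc}") from exc
    items = []
    for entry in raw_items:
        try:
            a = float(entry["a"])
            locs = [float(x) for x in entry["thresholds"]]
            if parameterization == "slope-intercept":
                locs = [-c / a for c in locs]
            items.append(ItemParameters(
                code=str(entry["code"]),
                model=model,
                a=a,
                thresholds=tuple(locs),
                raw_codes=tuple(str(c) for c in entry["raw_codes"]),
                instrument=str(entry.get("instrument", "")),
            ))
        except KeyError as exc:
            raise BankValidationError(
                f"item entry {entry.get('code', '?')!r} missing key {exc}"
            ) from exc
    return MetricBank(
        name=str(doc.get("name", "")),
        model=model,
        items=tuple(items),
        anchor_note=str(doc.get("anchor_note", "")),
        provenance=str(doc.get("provenance", "")),
        scaling_D=float(doc.get("scaling_D", 1.0)),
    )


def bank_to_dict(bank: MetricBank) -> dict:
    return {
        "name": bank.name,
        "model": bank.model,
        "scaling_D": bank.scaling_D,
        "anchor_note": bank.anchor_note,
        "provenance": bank.provenance,
        "items": [
            {
                "code": it.code,
                "instrument": it.instrument,
                "a": it.a,
                "thresholds": list(it.thresholds),
                "raw_codes": list(it.raw_codes),
            }
            for it in bank.items
        ],
    }


def load_bank(path: str | Path, *, parameterization: str = "irt") -> MetricBank:
    """Read and validate a bank JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return bank_from_dict(doc, parameterization=parameterization)


def save_bank(bank: MetricBank, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bank_to_dict(bank), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Response ingestion

def _cell_token(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    s = str(value).strip()
    # CSV readers hand back "2.0" for an integer-typed column; normalize.
    if s.endswith(".0"):
        s = s[:-2]
    return s


def ingest_responses(
    table: pd.DataFrame | str | Path,
    bank: MetricBank,
) -> tuple[ResponseMatrix, IngestionReport]:
    """Map a raw respondent table onto the bank's internal categories.

    Columns whose names match no item code (case-sensitive, exact) are
    dropped and listed in the report.  Cell values are matched against the
    item's raw response codes; empty cells and the tokens ``NA``/``na``
    are missing, and any other unmappable value becomes missing and is
    counted per column in the report.  Row order is preserved.

    Raises
    ------
    ValueError
        If no column matches any item code, or the table has duplicate
        column names.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype=str, keep_default_na=False,
                            skipinitialspace=True)
    cols = list(table.columns)
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate column names in data: {dupes}")
    code_set = set(bank.codes)
    retained = [c for c in cols if c in code_set]
    dropped = [c for c in cols if c not in code_set]
    if not retained:
        raise ValueError(
            f"no items of this metric found in data (bank {bank.name!r})")

    n = len(table)
    data = np.full((n, len(retained)), MISSING, dtype=np.int64)
    unmapped: dict[str, int] = {}
    for j, code in enumerate(retained):
        item = bank.item(code)
        lookup = {rc: k for k, rc in enumerate(item.raw_codes)}
        col = table[code].tolist()
        bad = 0
        for i, raw in enumerate(col):
            tok = _cell_token(raw)
            if tok in _MISSING_TOKENS:
                continue
            cat = lookup.get(tok, MISSING)
            if cat == MISSING:
                bad += 1
            data[i, j] = cat
        if bad:
            unmapped[code] = bad

    report = IngestionReport(
        retained_columns=tuple(retained),
        dropped_columns=tuple(dropped),
        n_rows=n,
        n_unmapped_cells=sum(unmapped.values()),
        unmapped_by_column=unmapped,
    )
    return ResponseMatrix(codes=tuple(retained), data=data), report
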