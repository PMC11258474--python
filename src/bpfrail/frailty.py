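"""Deficit-accumulation frailty index.

The frailty index (FI) is the proportion of health deficits an individual
has accrued out of those assessed: FI = (sum of non-missing deficit values)
/ (number of non-missing items). Categories follow the validated cutoffs
non-frail (FI < 0.12), pre-frail (0.12 <= FI <= 0.24), frail (FI > 0.24);
both boundary values fall in the pre-frail band, matching the closed middle
interval. A modified FI excluding cardiometabolic items and a
missing-item exclusion rule (drop persons with 10+ missing items) support
the sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "NON_FRAIL_MAX",
    "PRE_FRAIL_MAX",
    "compute_fi",
    "categorize_fi",
    "apply_missingness_filter",
    "default_cardiometabolic_items",
]

CATEGORIES = ["non_frail", "pre_frail", "frail"]
NON_FRAIL_MAX = 0.12  # FI < 0.12 -> non-frail
PRE_FRAIL_MAX = 0.24  # FI > 0.24 -> frail


@dataclass
class FrailtyResult:
    """Per-person FI values and categories.

    ``table`` columns: fi (NaN when every item is missing), n_items_answered,
    category (pd.Categorical, NaN for undefined FI). ``modified`` flags an FI
    computed on the cardiometabolic-excluded item subset.
    """

    table: pd.DataFrame
    modified: bool = False

    @property
    def fi(self) -> pd.Series:
        return self.table["fi"]

    @property
    def category(self) -> pd.Series:
        return self.table["category"]


def default_cardiometabolic_items(columns: list[str] | pd.Index) -> list[str]:
    """A labelled synthetic stand-in for the 8 cardiometabolic deficit items.

    The real item list lives in restricted supplementary material; for
    synthetic cohorts we designate the first 8 items as the cardiometabolic
    set. Any analysis on real data should supply its own list.
    """
    return list(columns[:8])


def compute_fi(
    deficits: pd.DataFrame,
    item_subset: list[str] | None = None,
    exclude_items: list[str] | None = None,
) -> FrailtyResult:
    """Compute the FI over (a subset of) deficit items.

    Parameters
    ----------
    deficits
        Persons x items; values in [0, 1], NaN = missing.
    item_subset
        Restrict to these columns (order irrelevant).
    exclude_items
        Drop these columns (e.g. the cardiometabolic set for the modified
        FI). Applied after ``item_subset``.

    Persons with every considered item missing get fi = NaN and no category;
    they are excluded downstream rather than silently zeroed.
    """
    items = deficits
    if item_subset is not None:
        items = items[list(item_subset)]
    modified = False
    if exclude_items:
        keep = [c for c in items.columns if c not in set(exclude_items)]
        if len(keep) == len(items.columns):
            raise ValueError("exclude_items matched no columns of the deficit table")
        items = items[keep]
        modified = True
    if items.shape[1] == 0:
        raise ValueError("no deficit items selected")

    vals = items.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0.0 or np.nanmax(vals, initial=0.0) > 1.0:
        raise ValueError("deficit values must lie in [0, 1]")

    answered = (~np.isnan(vals)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(vals, axis=1) / np.where(answered > 0, answered, np.nan)

    fi = pd.Series(fi, index=items.index, name="fi")
    table = pd.DataFrame(
        {
            "fi": fi,
            "n_items_answered": answered,
            "category": categorize_fi(fi, validate=False),
        },
        index=items.index,
    )
    return FrailtyResult(table=table, modified=modified)


def categorize_fi(fi, validate: bool = True) -> pd.Series:
    """Map FI values to non_frail / pre_frail / frail.

    fi < 0.12 -> non_frail; 0.12 <= fi <= 0.24 -> pre_frail; fi > 0.24 ->
    frail. NaN stays uncategorised.
    """
    arr = np.asarray(fi, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    finite = ~np.isnan(arr)
    if validate and ((arr[finite] < 0.0).any() or (arr[finite] > 1.0).any()):
        raise ValueError("FI values must lie in [0, 1]")
    codes = np.full(arr.shape, -1, dtype=int)
    codes[finite & (arr < NON_FRAIL_MAX)] = 0
    codes[finite & (arr >= NON_FRAIL_MAX) & (arr <= PRE_FRAIL_MAX)] = 1
    codes[finite & (arr > PRE_FRAIL_MAX)] = 2
    cat = pd.Categorical.from_codes(codes, categories=CATEGORIES, ordered=True)
    if scalar:
        return cat[0]
    return pd.Series(cat, index=fi.index if isinstance(fi, pd.Series) else None)


def apply_missingness_filter(deficits: pd.DataFrame, max_missing: int = 10) -> pd.Series:
    """Inclusion mask for the missing-item sensitivity analysis.

    Persons missing ``max_missing`` or more items are excluded (the default
    reproduces the "fewer than 10 missing items" rule).
    """
    n_missing = deficits.isna().sum(axis=1)
    return n_missing < max_missing
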