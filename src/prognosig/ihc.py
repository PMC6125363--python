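"""Immunohistochemistry combined scoring and region comparison.

Staining is rated per tumor region (invasive tumor front vs inner tumor)
on two ordinal scales — intensity 0-3 (negative/weak/moderate/strong) and
stained-cell percentage 0-3 (0%, <=25%, 26-50%, >50%) — whose sum gives a
combined score on 0-6. Subtracting the inner score from the ITF score
classifies each case as lower/equal/higher expression in the ITF; a case
with one unscored region is treated as equal. Inter-rater agreement over
the categorical calls uses Fleiss' multi-rater kappa, and associations
with clinical variables use Pearson chi-square crosstabs.

The category bin boundaries are a configurable convention (the field uses
several close variants); the defaults above are recorded in
``INTENSITY_BINS`` / ``PERCENTAGE_BINS``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as _sm_fleiss

from .errors import (
    DegenerateTableError,
    ParameterError,
    UndefinedKappaError,
    UnevaluableError,
)

INTENSITY_BINS = {0: "negative", 1: "weak", 2: "moderate", 3: "strong"}
PERCENTAGE_BINS = {0: "0%", 1: "<=25%", 2: "26-50%", 3: ">50%"}

CALLS = ("lower_in_ITF", "equal", "higher_in_ITF")


def combine_score(intensity: int, percentage: int) -> int:
    """Combined IHC score: intensity category + percentage category (0-6)."""
    for name, v in (("intensity", intensity), ("percentage", percentage)):
        if not (isinstance(v, (int, np.integer)) and 0 <= v <= 3):
            raise ParameterError(f"{name} category must be an integer in 0-3, got {v!r}")
    return int(intensity) + int(percentage)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def region_call(combined_itf, combined_inner) -> str:
    """Classify ITF expression relative to the inner tumor.

    The difference ITF - inner determines the call: negative = lower in
    the ITF, positive = higher, zero = equal. A case with exactly one
    missing region cannot be compared and is called equal; both missing
    is an error.
    """
    itf_missing, inner_missing = _is_missing(combined_itf), _is_missing(combined_inner)
    if itf_missing and inner_missing:
        raise UnevaluableError("both regions missing; case unevaluable")
    if itf_missing or inner_missing:
        return "equal"
    for name, v in (("combined_itf", combined_itf), ("combined_inner", combined_inner)):
        if not (0 <= v <= 6):
            raise ParameterError(f"{name} must be in 0-6, got {v!r}")
    diff = combined_itf - combined_inner
    if diff < 0:
        return "lower_in_ITF"
    if diff > 0:
        return "higher_in_ITF"
    return "equal"


def rater_calls(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-rater region calls (cases x raters) from a long rating table.

    ``ratings`` has columns ``case, rater, region, intensity, percentage``;
    each rater's combined scores per region feed :func:`region_call`.
    """
    combined = ratings.assign(
        combined=[
            combine_score(i, p) for i, p in zip(ratings["intensity"], ratings["percentage"])
        ]
    )
    wide = combined.pivot_table(
        index=["case", "rater"], columns="region", values="combined", aggfunc="first"
    )
    calls = wide.apply(
        lambda row: region_call(row.get("ITF", float("nan")), row.get("inner", float("nan"))),
        axis=1,
    )
    return calls.unstack("rater")


def fleiss_kappa(ratings: pd.DataFrame) -> float:
    """Fleiss' multi-rater kappa over categorical calls (cases x raters)."""
    if ratings.shape[1] < 2 or ratings.shape[0] < 2:
        raise ParameterError("need >= 2 raters and >= 2 cases")
    table, _cats = aggregate_raters(ratings.to_numpy())
    if table.shape[1] < 2:
        raise UndefinedKappaError("all ratings fall in a single category")
    return float(_sm_fleiss(table, method="fleiss"))


def crosstab_chisq(calls, clinical) -> dict:
    """Pearson chi-square test of a calls x clinical contingency table.

    No continuity correction (matching the classic crosstab test);
    returns the table alongside chi2, df and p. Zero row/column marginals
    are an error — collapse sparse categories first.
    """
    table = pd.crosstab(
        pd.Series(np.asarray(calls), name="call"),
        pd.Series(np.asarray(clinical), name="clinical"),
    )
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError("contingency table needs >= 2 rows and columns")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero marginal")
    chi2, p, df, _exp = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"chi2": float(chi2), "df": int(df), "p_value": float(p), "table": table}
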