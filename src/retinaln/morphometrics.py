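"""Ribbon morphometrics: per-group size summaries and the volume-vesicle
count regression.

The regression direction is explicit because a slope of order 1e-6 um^3 per
vesicle is only dimensionally sensible with volume as the response; both
directions are supported and tested.  Quartiles use the linear-interpolation
convention throughout (numpy default), stated here because violin/box
conventions vary across tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, ParameterError
from .synth import RibbonRecord

__all__ = [
    "RegressionFit",
    "GroupSummary",
    "records_frame",
    "fit_ribbon_regression",
    "summarize_groups",
]


@dataclass
class RegressionFit:
    """Ordinary-least-squares line fit with inference on the slope."""

    slope: float
    intercept: float
    r_squared: float
    p_value_slope: float
    n: int
    predictor: str
    response: str


@dataclass
class GroupSummary:
    """Five-number-style summary of one group (median, quartiles, whiskers
    at 1.5 IQR clipped to the data range)."""

    group: str
    n: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float


def records_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of ribbon records (volume_um3, vesicle_count,
    bipolar_type, target)."""
    rows = [
        (r.ribbon_volume, r.vesicle_count, r.bipolar_type, r.target)
        for r in records
    ]
    if not rows:
        raise ParameterError("no ribbon records")
    return pd.DataFrame(
        rows, columns=["volume_um3", "vesicle_count", "bipolar_type", "target"]
    )


_COLUMNS = {"volume": "volume_um3", "count": "vesicle_count"}


def fit_ribbon_regression(
    records,
    predictor: str = "count",
    response: str = "volume",
) -> RegressionFit:
    """OLS fit of ribbon volume against vesicle count (default direction)
    or the reverse.

    Returns slope, intercept, r-squared and the two-sided p-value of the
    slope t-statistic.
    """
    if predictor not in _COLUMNS or response not in _COLUMNS or predictor == response:
        raise ParameterError("predictor/response must be 'volume' and 'count'")
    df = records_frame(records)
    x = df[_COLUMNS[predictor]].to_numpy(dtype=float)
    y = df[_COLUMNS[response]].to_numpy(dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 records for the regression")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant predictor: regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value_slope=float(model.pvalues[1]),
        n=int(x.size),
        predictor=predictor,
        response=response,
    )


def summarize_groups(
    records,
    group_by: str = "bipolar_type",
    value: str = "volume",
) -> list[GroupSummary]:
    """Median/quartile/whisker summary of ribbon volume (or count) per
    bipolar type or per postsynaptic target."""
    if group_by not in ("bipolar_type", "target"):
        raise ParameterError("group_by must be 'bipolar_type' or 'target'")
    if value not in _COLUMNS:
        raise ParameterError("value must be 'volume' or 'count'")
    df = records_frame(records)
    out: list[GroupSummary] = []
    for label in sorted(df[group_by].unique()):
        vals = df.loc[df[group_by] == label, _COLUMNS[value]].to_numpy(dtype=float)
        q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q75 - q25
        out.append(
            GroupSummary(
                group=str(label),
                n=int(vals.size),
                median=float(med),
                q25=float(q25),
                q75=float(q75),
                whisker_low=float(max(vals.min(), q25 - 1.5 * iqr)),
                whisker_high=float(min(vals.max(), q75 + 1.5 * iqr)),
            )
        )
    return out
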