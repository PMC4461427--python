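"""End-of-record rates of change and the end-year truncation comparison.

Fitting the same record truncated at two different end years and comparing
the rate of change at each end answers whether the trend visible in the
shorter record kept its pace once another decade of data is added.  For
phenology (advancing onset = negative rate), a *negative* difference
``rate_short - rate_long`` means the advancing trend slowed down; for
temperature (warming = positive rate), a *positive* difference means the
warming trend slowed down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .average import analyze
from .io import RunConfig, TimeSeries, truncate_series

__all__ = ["TrendComparison", "endpoint_rate", "compare_end_years", "CLASSIFICATION_TOL"]

#: rate differences below this (units/year) count as "unchanged" — below the
#: resolution of a two-decimal printed rate
CLASSIFICATION_TOL = 0.005


@dataclass(frozen=True)
class TrendComparison:
    label: str
    variable_kind: str
    end_year_short: int
    end_year_long: int
    rate_short: float  # units/year at the short record's last observation
    rate_long: float
    delta: float  # rate_short - rate_long
    classification: str  # slowdown | intensification | unchanged


def classify_delta(delta: float, variable_kind: str, tol: float = CLASSIFICATION_TOL) -> str:
    """Sign rule for the truncation difference.

    Phenology: delta < -tol means the advancing (negative) trend weakened in
    the longer record -> slowdown.  Temperature: delta > +tol means the
    warming trend weakened -> slowdown.  Within +-tol -> unchanged.
    """
    if abs(delta) <= tol:
        return "unchanged"
    if variable_kind == "phenology":
        return "slowdown" if delta < 0 else "intensification"
    return "slowdown" if delta > 0 else "intensification"


def endpoint_rate(s: TimeSeries, cfg: RunConfig = RunConfig()) -> float:
    """Model-averaged rate of change at the last observed year of the record."""
    last = float(s.years[-1])
    res = analyze(s, replace(cfg, grid=np.array([last]), end_year=None), bands=False)
    return float(res.estimate.deriv_mean[-1])


def compare_end_years(
    s: TimeSeries, end_short: int, end_long: int, cfg: RunConfig = RunConfig()
) -> TrendComparison:
    """Fit the record truncated at two end years and difference the end rates.

    Both truncations are analyzed completely independently (same priors,
    same RunConfig); the returned delta is rate_short - rate_long with the
    qualitative classification per variable kind.
    """
    if not end_short < end_long <= int(s.years[-1]):
        raise ValueError(
            f"need end_short < end_long <= last observed year "
            f"({end_short}, {end_long}, {int(s.years[-1])})"
        )
    s_short = truncate_series(s, end_short)
    s_long = truncate_series(s, end_long)
    rate_short = endpoint_rate(s_short, cfg)
    rate_long = endpoint_rate(s_long, cfg)
    delta = rate_short - rate_long
    return TrendComparison(
        label=s.label,
        variable_kind=s.variable_kind,
        end_year_short=int(s_short.years[-1]),
        end_year_long=int(s_long.years[-1]),
        rate_short=rate_short,
        rate_long=rate_long,
        delta=delta,
        classification=classify_delta(delta, s.variable_kind),
    )
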