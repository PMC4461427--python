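"""Annual time series containers, CSV input, truncation, and result output.

The analysis operates on annual records: one value per calendar year, with
years possibly missing.  Phenological values are day-of-year (DOY, 1 = Jan 1)
flowering onset dates; temperature values are seasonal means in degrees
Celsius.  Input files are plain two-column CSV (year, value); rows with an
empty value field denote missing years and are dropped on read.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "RunConfig",
    "read_series",
    "truncate_series",
    "write_results",
    "read_results",
]

#: Minimum usable record length: the smallest N for which the constant,
#: linear, one- and two-change-point classes are all evaluable.
MIN_OBSERVATIONS = 4

VARIABLE_KINDS = ("phenology", "temperature")


@dataclass(frozen=True)
class TimeSeries:
    """An annual record for one station and variable.

    Parameters
    ----------
    years : array of int
        Calendar years, strictly increasing.  Gaps are allowed and simply
        absent; no imputation happens anywhere downstream.
    values : array of float
        Day-of-year (phenology) or degrees Celsius (temperature).
    variable_kind : {"phenology", "temperature"}
    label : str
        Free-text identifier (station, phase or temperature window).
    """

    years: np.ndarray
    values: np.ndarray
    variable_kind: str = "phenology"
    label: str = ""

    def __post_init__(self):
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.variable_kind not in VARIABLE_KINDS:
            raise ValueError(
                f"variable_kind must be one of {VARIABLE_KINDS}, "
                f"got {self.variable_kind!r}"
            )
        if years.ndim != 1 or values.shape != years.shape:
            raise ValueError("years and values must be 1-D and equal length")
        if len(years) < MIN_OBSERVATIONS:
            raise ValueError(
                f"too few observations: need at least {MIN_OBSERVATIONS}, "
                f"got {len(years)}"
            )
        if np.any(np.diff(years) <= 0):
            bad = years[1:][np.diff(years) <= 0][0]
            raise ValueError(f"years must be strictly increasing (around year {bad})")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.variable_kind == "phenology" and (
            np.any(values < 1.0) or np.any(values > 366.0)
        ):
            raise ValueError("phenology values must be day-of-year in [1, 366]")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def n(self) -> int:
        return len(self.years)

    @property
    def value_range(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass(frozen=True)
class RunConfig:
    """Settings for one analysis run.

    All randomness (Monte Carlo configuration sampling, posterior draws)
    flows from ``seed``; re-running with the same seed reproduces every
    number bit for bit.
    """

    max_cpt: int = 2
    end_year: Optional[int] = None
    grid: Optional[np.ndarray] = None
    n_mc: int = 10_000
    n_draws: int = 2_000
    seed: int = 0
    credible_level: float = 0.95
    #: relative widening of the coefficient prior beyond the data range
    prior_margin: float = 0.05
    #: enumerate exactly when the configuration count is at most this
    enum_limit: int = 100_000

    def __post_init__(self):
        if self.max_cpt < 0:
            raise ValueError("max_cpt must be >= 0")
        if self.n_mc < 1 or self.n_draws < 1:
            raise ValueError("n_mc and n_draws must be >= 1")
        if not (0.0 < self.credible_level < 1.0):
            raise ValueError("credible_level must be in (0, 1)")
        if self.grid is not None:
            object.__setattr__(
                self, "grid", np.asarray(self.grid, dtype=np.float64)
            )

    def grid_for(self, s: TimeSeries) -> np.ndarray:
        """Evaluation grid: explicit grid if set, else every year of the record."""
        if self.grid is not None:
            return self.grid
        return np.arange(s.years[0], s.years[-1] + 1, dtype=np.float64)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def read_series(path, variable_kind: str = "phenology", label: str = "") -> TimeSeries:
    """Read a two-column (year, value) CSV into a validated :class:`TimeSeries`.

    An optional header line is detected by a non-numeric first field.  Rows
    whose value field is empty are treated as missing years and dropped.

    Raises
    ------
    ValueError
        On duplicate years (naming the year), non-numeric values (naming the
        line), or fewer than four usable rows.
    """
    path = Path(path)
    years: list[int] = []
    values: list[float] = []
    seen: set[int] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            y_field, v_field = row[0].strip(), row[1].strip()
            try:
                year = int(y_field)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric year {y_field!r}"
                ) from None
            if year in seen:
                raise ValueError(f"{path}: duplicate year {year}")
            seen.add(year)
            if v_field == "":
                continue  # missing year
            try:
                value = float(v_field)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value {v_field!r}"
                ) from None
            years.append(year)
            values.append(value)
    if len(years) < MIN_OBSERVATIONS:
        raise ValueError(
            f"{path}: too few observations ({len(years)} < {MIN_OBSERVATIONS})"
        )
    order = np.argsort(years)
    return TimeSeries(
        years=np.asarray(years)[order],
        values=np.asarray(values)[order],
        variable_kind=variable_kind,
        label=label or path.stem,
    )


def truncate_series(s: TimeSeries, end_year: int) -> TimeSeries:
    """Return the sub-series of observations with ``year <= end_year``.

    The original series is unchanged.  Raises if fewer than four
    observations would remain.
    """
    keep = s.years <= end_year
    if keep.sum() < MIN_OBSERVATIONS:
        raise ValueError(
            f"truncation at {end_year} leaves {int(keep.sum())} observations "
            f"(< {MIN_OBSERVATIONS})"
        )
    return TimeSeries(
        years=s.years[keep],
        values=s.values[keep],
        variable_kind=s.variable_kind,
        label=s.label,
    )


# full repr precision so that write -> read round-trips exactly
_FMT = "%.17g"


def write_results(fit, posterior, path, quality=None) -> None:
    """Write an analysis to ``<path>.csv`` (grid curves) and ``<path>.json``.

    The CSV holds one row per grid year: fit mean and standard error, the
    rate-of-change (derivative) mean and standard error, and the sampled
    credible bounds for both.  The JSON block carries the model-class
    probabilities, the end-of-series rate, and (when supplied) the model
    efficiency.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "year": fit.grid,
            "fit_mean": fit.mean,
            "fit_sd": fit.sd,
            "deriv_mean": fit.deriv_mean,
            "deriv_sd": fit.deriv_sd,
            "fit_lo": fit.credible_lo,
            "fit_hi": fit.credible_hi,
            "deriv_lo": fit.deriv_credible_lo,
            "deriv_hi": fit.deriv_credible_hi,
        }
    )
    frame.to_csv(base.with_suffix(".csv"), index=False, float_format=_FMT)
    summary = {
        "model_probabilities": {
            c: float(p) for c, p in zip(posterior.classes, posterior.probabilities)
        },
        "end_rate": float(fit.deriv_mean[-1]),
    }
    if quality is not None:
        summary["model_efficiency"] = float(quality.me)
        summary["ss_tot"] = float(quality.ss_tot)
        summary["ss_res"] = float(quality.ss_res)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")


def read_results(path):
    """Read back the ``write_results`` pair as ``(DataFrame, dict)``."""
    base = Path(path)
    frame = pd.read_csv(base.with_suffix(".csv"), float_precision="round_trip")
    with open(base.with_suffix(".json")) as fh:
        summary = json.load(fh)
    return frame, summary
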