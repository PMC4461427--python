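"""Synthetic annual series with known piecewise-linear structure.

The generator emulates the statistical shape of century-long phenological
and seasonal-temperature records: ~100-112 annual values with irregular
gaps, a continuous piecewise-linear mean whose break sits in the early/mid
1980s, and independent Gaussian year-to-year noise (several days for
flowering onset, about 1 degree C for seasonal temperature means).  Because
the true mean and slopes are returned alongside the data, every analysis
stage can be tested against known truth, and `recovery_experiment` runs the
whole fit repeatedly to measure model-selection frequency, change-point
location error, and end-rate error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .average import analyze
from .core import class_labels
from .io import RunConfig, TimeSeries

__all__ = [
    "SyntheticSpec",
    "PiecewiseTruth",
    "generate_piecewise_series",
    "generate_paired_pheno_temp",
    "recovery_experiment",
    "coverage_experiment",
    "truncation_experiment",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating model for one annual record.

    Defaults mirror the study conditions of a long German phenological
    record: 1901-2012, one break in 1985, flat then advancing at
    -0.5 days/year, 5 days of interannual noise, ~5% of years missing.
    """

    start_year: int = 1901
    end_year: int = 2012
    breakpoints: tuple = (1985,)
    level_at_start: float = 60.0
    slopes: tuple = (0.0, -0.5)
    noise_sd: float = 5.0
    missing_frac: float = 0.05
    variable_kind: str = "phenology"
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", tuple(self.breakpoints))
        object.__setattr__(self, "slopes", tuple(self.slopes))
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more slope than breakpoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_frac < 0.3):
            raise ValueError("missing_frac must be in [0, 0.3)")
        if any(
            not (self.start_year < b < self.end_year) for b in self.breakpoints
        ) or any(b >= c for b, c in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be increasing interior years")

    @property
    def n_segments(self) -> int:
        return len(self.slopes)


@dataclass(frozen=True)
class PiecewiseTruth:
    """The generating mean polygon, for oracle use in tests and experiments."""

    pivot_years: np.ndarray  # start, breakpoints..., end
    pivot_values: np.ndarray
    slopes: np.ndarray  # per segment

    def mean(self, years) -> np.ndarray:
        return np.interp(np.asarray(years, dtype=float), self.pivot_years, self.pivot_values)

    def slope(self, years) -> np.ndarray:
        """Left-slope convention at the breakpoints, matching the fit."""
        years = np.asarray(years, dtype=float)
        seg = np.clip(
            np.searchsorted(self.pivot_years, years, side="left") - 1,
            0,
            len(self.slopes) - 1,
        )
        return self.slopes[seg]

    @property
    def end_slope(self) -> float:
        return float(self.slopes[-1])


def _truth_from_spec(spec: SyntheticSpec) -> PiecewiseTruth:
    pivots = np.array(
        [spec.start_year, *spec.breakpoints, spec.end_year], dtype=float
    )
    values = [spec.level_at_start]
    for seg in range(spec.n_segments):
        values.append(values[-1] + spec.slopes[seg] * (pivots[seg + 1] - pivots[seg]))
    return PiecewiseTruth(
        pivot_years=pivots,
        pivot_values=np.array(values),
        slopes=np.array(spec.slopes, dtype=float),
    )


def generate_piecewise_series(spec: SyntheticSpec):
    """Draw one annual record from the spec: (TimeSeries, PiecewiseTruth).

    Values are the continuous piecewise-linear mean plus iid Gaussian noise;
    a ``missing_frac`` share of interior years is dropped at random (the
    first and last year are always retained so the record span is the
    spec's).  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_from_spec(spec)
    years = np.arange(spec.start_year, spec.end_year + 1)
    n_drop = int(round(spec.missing_frac * len(years)))
    if n_drop > 0:
        interior = np.arange(1, len(years) - 1)
        drop = rng.choice(interior, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(len(years)), drop)
        years = years[keep]
    if len(years) < 4:
        raise ValueError("retained year set too small")
    values = truth.mean(years) + rng.normal(0.0, spec.noise_sd, len(years))
    series = TimeSeries(
        years=years,
        values=values,
        variable_kind=spec.variable_kind,
        label=spec.label,
    )
    return series, truth


def generate_paired_pheno_temp(
    spec_t: SyntheticSpec,
    sensitivity: float,
    pheno_noise_sd: float,
    seed: int,
    baseline: float = 60.0,
):
    """Temperature record plus a phenology record driven by it.

    The phenology value in year t is ``baseline + sensitivity * (T_t -
    Tbar) + noise`` with Tbar the mean of the true temperature mean over the
    record, so temperature change points propagate into phenology with
    slopes scaled by ``sensitivity`` (days per degree C; typically negative:
    warmer springs, earlier flowering).  Both records share the retained
    years.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    temp, truth_t = generate_piecewise_series(
        replace(spec_t, variable_kind="temperature", seed=int(ss[0].generate_state(1)[0] % 2**31))
    )
    rng = np.random.default_rng(ss[1])
    tbar = float(np.mean(truth_t.mean(np.arange(spec_t.start_year, spec_t.end_year + 1))))
    pheno_values = (
        baseline
        + sensitivity * (temp.values - tbar)
        + rng.normal(0.0, pheno_noise_sd, len(temp))
    )
    pheno = TimeSeries(
        years=temp.years,
        values=pheno_values,
        variable_kind="phenology",
        label=f"{spec_t.label}-pheno",
    )
    return temp, pheno


def _generating_class(spec: SyntheticSpec) -> str:
    if len(spec.breakpoints) == 0:
        if all(sl == 0.0 for sl in spec.slopes):
            return "constant"
        return "linear"
    return f"{len(spec.breakpoints)}cpt"


def recovery_experiment(
    spec: SyntheticSpec,
    n_reps: int,
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Generate-fit-score loop measuring what the analysis recovers.

    Per replicate: draw a record, run the full model comparison, and record
    the selected class, the posterior-weighted one-change-point location,
    and the end-of-record rate.  Returns selection frequencies, the
    change-point location MAE (replicates only scored when the generating
    model has exactly one break), and end-rate bias / RMSE against the
    generating end slope.  Bit-reproducible under ``cfg.seed``.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50 for stable frequencies")
    truth = _truth_from_spec(spec)
    gen_class = _generating_class(spec)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_reps) % (2**31)
    selected = []
    loc_err = []
    rate_err = []
    mean_probs = None
    for r in range(n_reps):
        series, _ = generate_piecewise_series(replace(spec, seed=int(seeds[r])))
        last = float(series.years[-1])
        res = analyze(
            series,
            replace(cfg, seed=int(seeds[r]), grid=np.array([last])),
            bands=False,
        )
        selected.append(res.posterior.best)
        probs = np.asarray(res.posterior.probabilities)
        mean_probs = probs if mean_probs is None else mean_probs + probs
        rate_err.append(float(res.estimate.deriv_mean[-1]) - truth.end_slope)
        if len(spec.breakpoints) == 1:
            loc_err.append(res.cpt_location("1cpt") - spec.breakpoints[0])
    mean_probs = mean_probs / n_reps
    classes = class_labels(cfg.max_cpt)
    sel = np.asarray(selected)
    rate_err = np.asarray(rate_err)
    out = {
        "n_reps": n_reps,
        "generating_class": gen_class,
        "selection_freq": {c: float((sel == c).mean()) for c in classes},
        "mean_class_probs": {c: float(p) for c, p in zip(classes, mean_probs)},
        "end_rate_bias": float(rate_err.mean()),
        "end_rate_rmse": float(np.sqrt((rate_err**2).mean())),
    }
    if loc_err:
        out["cpt_location_mae"] = float(np.abs(np.asarray(loc_err)).mean())
    return out


def coverage_experiment(
    spec: SyntheticSpec,
    n_reps: int,
    cfg: RunConfig = RunConfig(),
    at_fraction: float = 0.5,
) -> dict:
    """How often the credible band covers the true mean at one grid year.

    Per replicate the record is generated, the full posterior is sampled at
    a single evaluation year (``at_fraction`` of the way through the
    record), and a hit is recorded when the central band at
    ``cfg.credible_level`` contains the generating mean there.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50 for stable frequencies")
    truth = _truth_from_spec(spec)
    at_year = float(
        round(spec.start_year + at_fraction * (spec.end_year - spec.start_year))
    )
    target = float(truth.mean([at_year])[0])
    seeds = np.random.SeedSequence(cfg.seed + 1).generate_state(n_reps) % (2**31)
    hits = 0
    for r in range(n_reps):
        series, _ = generate_piecewise_series(replace(spec, seed=int(seeds[r])))
        res = analyze(
            series,
            replace(cfg, seed=int(seeds[r]), grid=np.array([at_year])),
            bands=True,
        )
        lo = float(res.estimate.credible_lo[0])
        hi = float(res.estimate.credible_hi[0])
        hits += int(lo <= target <= hi)
    return {
        "n_reps": n_reps,
        "at_year": at_year,
        "true_mean": target,
        "coverage": hits / n_reps,
        "nominal": cfg.credible_level,
    }


def truncation_experiment(
    spec: SyntheticSpec,
    n_reps: int,
    end_short: int,
    end_long: int,
    cfg: RunConfig = RunConfig(),
) -> dict:
    """End-year comparison over replicates: classification frequencies.

    Generates records from ``spec`` (which should place a trend change
    between the two end years, e.g. a post-``end_short`` flattening), runs
    the two-truncation comparison on each, and tallies how often each
    qualitative outcome (slowdown / intensification / unchanged) occurs,
    along with the mean rate difference.
    """
    from .trends import compare_end_years

    if n_reps < 50:
        raise ValueError("n_reps must be >= 50 for stable frequencies")
    seeds = np.random.SeedSequence(cfg.seed + 2).generate_state(n_reps) % (2**31)
    outcomes = []
    deltas = []
    for r in range(n_reps):
        series, _ = generate_piecewise_series(replace(spec, seed=int(seeds[r])))
        comp = compare_end_years(
            series, end_short, end_long, replace(cfg, seed=int(seeds[r]))
        )
        outcomes.append(comp.classification)
        deltas.append(comp.delta)
    outcomes = np.asarray(outcomes)
    return {
        "n_reps": n_reps,
        "freq": {
            c: float((outcomes == c).mean())
            for c in ("slowdown", "intensification", "unchanged")
        },
        "mean_delta": float(np.mean(deltas)),
    }
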