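"""Change-point configurations, piecewise-linear bases, and Bayesian evidence.

A trend model for an annual record of N observations is a continuous
piecewise-linear "polygon": ``n_cpt`` interior change points plus the two
record endpoints give ``n_p = n_cpt + 2`` pivots, and the fitted function is
linear between adjacent pivots.  The constant model is the degenerate
``n_p = 1`` case (a single level).  Change points are restricted to observed
years strictly inside the record, so one change point admits exactly N - 2
configurations and ``n_cpt`` change points admit C(N-2, n_cpt).

For each configuration the polygon vertex values enter the likelihood
linearly through a "hat" (linear interpolation) basis, so the per-
configuration posterior is conjugate: with a flat coefficient prior of
normalization width Delta per pivot and a Jeffreys 1/sigma prior on the
Gaussian noise scale, the marginal likelihood (evidence) of configuration c
with design matrix A, Gram matrix G = A'A, and least-squares residual sum
``rss`` is

    E(c) = Delta^-M (2 pi)^-(nu/2) |G|^-1/2 (1/2) Gamma(nu/2) (rss/2)^-(nu/2)

with M coefficients and nu = N - M residual degrees of freedom.  The
``Delta^-M`` factor is the Ockham penalty that lets model classes of
different dimension compete on one scale.  All evidence arithmetic is done
in log space: ``rss^-(nu/2)`` overflows at N ~ 110 otherwise.

Configuration sums (class evidences, model-averaged curves) are evaluated by
exact enumeration whenever the configuration count is small enough, and by
uniform Monte Carlo sampling of configurations with evidence weights
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.special import comb, gammaln, logsumexp

from .io import TimeSeries

__all__ = [
    "PivotConfig",
    "ConfigFit",
    "enumerate_configs",
    "build_basis",
    "least_squares_fit",
    "log_evidence",
    "sample_configs_mc",
    "n_configurations",
    "class_labels",
    "class_dim",
    "fit_model_class",
    "ClassFits",
    "MCSample",
]

# rss below this fraction of the squared data scale counts as an exact fit
_EXACT_RSS_REL = 1e-18


# ---------------------------------------------------------------------------
# configurations


@dataclass(frozen=True)
class PivotConfig:
    """One placement of interior change points.

    ``n_p = n_cpt + 2`` pivots for segment models; the constant model is
    represented by ``n_p = 1`` and no change points.
    """

    n_cpt: int
    cpt_years: tuple
    n_p: int = -1  # filled in __post_init__ unless constant

    def __post_init__(self):
        object.__setattr__(self, "cpt_years", tuple(int(y) for y in self.cpt_years))
        if self.n_p == -1:
            object.__setattr__(self, "n_p", self.n_cpt + 2)
        if self.n_p == 1:
            if self.cpt_years:
                raise ValueError("constant model (n_p = 1) has no change points")
        elif self.n_p != self.n_cpt + 2:
            raise ValueError("segment models require n_p = n_cpt + 2")
        if len(self.cpt_years) != (0 if self.n_p <= 2 else self.n_cpt):
            raise ValueError("cpt_years length must equal n_cpt")
        if any(b <= a for a, b in zip(self.cpt_years, self.cpt_years[1:])):
            raise ValueError("cpt_years must be strictly increasing")

    @classmethod
    def constant(cls) -> "PivotConfig":
        return cls(n_cpt=0, cpt_years=(), n_p=1)

    @classmethod
    def linear(cls) -> "PivotConfig":
        return cls(n_cpt=0, cpt_years=())

    @property
    def is_constant(self) -> bool:
        return self.n_p == 1

    @property
    def n_coef(self) -> int:
        return self.n_p

    def pivots_for(self, s: TimeSeries) -> Optional[np.ndarray]:
        """Pivot year vector (endpoints plus change points); None if constant."""
        if self.is_constant:
            return None
        interior = set(map(int, s.years[1:-1]))
        for y in self.cpt_years:
            if y not in interior:
                raise ValueError(
                    f"change point {y} is not an interior observed year of the series"
                )
        return np.concatenate(
            ([s.years[0]], np.asarray(self.cpt_years), [s.years[-1]])
        ).astype(np.float64)


@dataclass(frozen=True)
class ConfigFit:
    """Least-squares polygon and evidence ingredients for one configuration."""

    config: PivotConfig
    coefficients: np.ndarray  # fitted function values at the pivots
    rss: float
    gram_logdet: float
    log_evidence: Optional[float] = None


def n_configurations(n_cpt: int, n_obs: int) -> int:
    """Number of change-point placements: C(N-2, n_cpt)."""
    return int(comb(n_obs - 2, n_cpt, exact=True))


def enumerate_configs(n_cpt: int, s: TimeSeries) -> list:
    """All C(N-2, n_cpt) placements of interior change points at observed years.

    ``n_cpt = 0`` yields the single empty configuration (the linear model).
    """
    if n_cpt < 0 or n_cpt > len(s) - 3:
        raise ValueError(
            f"n_cpt must satisfy 0 <= n_cpt <= N - 3 = {len(s) - 3}, got {n_cpt}"
        )
    interior = [int(y) for y in s.years[1:-1]]
    return [PivotConfig(n_cpt, c) for c in combinations(interior, n_cpt)]


# ---------------------------------------------------------------------------
# batch basis / least-squares machinery
#
# P is a (ncfg, n_p) matrix of pivot years (first and last columns are the
# record endpoints).  All configurations of one model class share n_p, so a
# whole class is fitted with stacked linear algebra.


def _segment_index(P: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Left-slope segment index of each t in each pivot row: (ncfg, T).

    For t exactly at an interior pivot, the segment to its *left* is
    returned; values are clipped into [0, n_p - 2].
    """
    # count pivots strictly below t -> searchsorted 'left' semantics
    seg = (P[:, :, None] < t[None, None, :]).sum(axis=1) - 1
    return np.clip(seg, 0, P.shape[1] - 2)


def _basis_stack(P: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Hat-function design matrices, stacked: (ncfg, T, n_p).

    Column j is 1 at pivot j, 0 at the other pivots, linear between
    neighbours.  Rows sum to one (partition of unity).
    """
    ncfg, n_p = P.shape
    seg = _segment_index(P, t)
    left = np.take_along_axis(P, seg, axis=1)
    right = np.take_along_axis(P, seg + 1, axis=1)
    w = (t[None, :] - left) / (right - left)
    A = np.zeros((ncfg, len(t), n_p))
    rows = np.arange(ncfg)[:, None]
    cols = np.arange(len(t))[None, :]
    A[rows, cols, seg] = 1.0 - w
    A[rows, cols, seg + 1] = w
    return A


def _slope_stack(P: np.ndarray, coef: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Polygon slope at each t (left-slope at pivots), stacked: (ncfg, T)."""
    seg = _segment_index(P, t)
    left = np.take_along_axis(P, seg, axis=1)
    right = np.take_along_axis(P, seg + 1, axis=1)
    cl = np.take_along_axis(coef, seg, axis=1)
    cr = np.take_along_axis(coef, seg + 1, axis=1)
    return (cr - cl) / (right - left)


def _slope_functional_stack(P: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Rows d with slope(t) = d . coef, stacked: (ncfg, T, n_p)."""
    ncfg, n_p = P.shape
    seg = _segment_index(P, t)
    left = np.take_along_axis(P, seg, axis=1)
    right = np.take_along_axis(P, seg + 1, axis=1)
    inv = 1.0 / (right - left)
    D = np.zeros((ncfg, len(t), n_p))
    rows = np.arange(ncfg)[:, None]
    cols = np.arange(len(t))[None, :]
    D[rows, cols, seg] = -inv
    D[rows, cols, seg + 1] = inv
    return D


def _fit_stack(P: np.ndarray, s: TimeSeries):
    """Stacked least squares for every pivot row in P.

    Returns (coef, rss, gram_logdet, G) with shapes
    (ncfg, n_p), (ncfg,), (ncfg,), (ncfg, n_p, n_p).
    """
    x = s.years.astype(np.float64)
    y = s.values
    A = _basis_stack(P, x)
    G = np.einsum("cnm,cnp->cmp", A, A)
    b = np.einsum("cnm,n->cm", A, y)
    sign, logdet = np.linalg.slogdet(G)
    if np.any(sign <= 0):
        bad = int(np.argmax(sign <= 0))
        raise np.linalg.LinAlgError(
            f"singular Gram matrix for configuration with pivots {P[bad]}"
        )
    coef = np.linalg.solve(G, b[..., None])[..., 0]
    resid = y[None, :] - np.einsum("cnm,cm->cn", A, coef)
    rss = np.einsum("cn,cn->c", resid, resid)
    return coef, rss, logdet, G


def _fit_constant(s: TimeSeries):
    """Constant model: single all-ones column; coefficient is the mean."""
    y = s.values
    mean = float(y.mean())
    rss = float(((y - mean) ** 2).sum())
    return (
        np.array([[mean]]),
        np.array([rss]),
        np.array([math.log(len(s))]),
        np.full((1, 1, 1), float(len(s))),
    )


# ---------------------------------------------------------------------------
# single-configuration API


def build_basis(config: PivotConfig, s: TimeSeries) -> np.ndarray:
    """Design matrix (N x M) of hat functions at the observation years."""
    if config.is_constant:
        return np.ones((len(s), 1))
    P = config.pivots_for(s)[None, :]
    return _basis_stack(P, s.years.astype(np.float64))[0]


def least_squares_fit(config: PivotConfig, s: TimeSeries) -> ConfigFit:
    """Least-squares polygon for one configuration.

    The coefficients are the fitted function values at the pivots; ``rss``
    and the log-determinant of the Gram matrix are what the evidence needs.
    """
    if config.is_constant:
        coef, rss, logdet, _ = _fit_constant(s)
    else:
        P = config.pivots_for(s)[None, :]
        coef, rss, logdet, _ = _fit_stack(P, s)
    return ConfigFit(
        config=config,
        coefficients=coef[0],
        rss=float(rss[0]),
        gram_logdet=float(logdet[0]),
    )


def _prior_width(s: TimeSeries, prior_margin: float) -> float:
    raw = s.value_range
    if raw <= 0:
        raise ValueError("degenerate series: all values equal, prior width is zero")
    return (1.0 + 2.0 * prior_margin) * raw


def _exact_rss_tol(s: TimeSeries) -> float:
    return _EXACT_RSS_REL * max(1.0, float((s.values**2).sum()))


def _log_evidence_arr(
    rss: np.ndarray, gram_logdet: np.ndarray, n_obs: int, m: int, delta: float
) -> np.ndarray:
    nu = n_obs - m
    with np.errstate(divide="ignore"):
        return (
            -m * math.log(delta)
            - 0.5 * nu * math.log(2.0 * math.pi)
            - 0.5 * gram_logdet
            - math.log(2.0)
            + gammaln(0.5 * nu)
            - 0.5 * nu * np.log(0.5 * rss)
        )


def log_evidence(fit: ConfigFit, s: TimeSeries, prior_margin: float = 0.05) -> float:
    """Log marginal likelihood of one configuration.

    Integrates the Gaussian likelihood over the polygon vertex values (flat
    prior of width Delta per coefficient) and over the noise scale (Jeffreys
    1/sigma), in closed form.  Requires at least one residual degree of
    freedom and a strictly positive residual sum.
    """
    m = fit.config.n_coef
    if len(s) - m < 1:
        raise ValueError(f"need N - M >= 1 (N={len(s)}, M={m})")
    if fit.rss <= _exact_rss_tol(s):
        raise ValueError(
            "degenerate exact fit: rss = 0, evidence diverges "
            f"(configuration {fit.config.cpt_years})"
        )
    delta = _prior_width(s, prior_margin)
    return float(
        _log_evidence_arr(
            np.asarray([fit.rss]), np.asarray([fit.gram_logdet]), len(s), m, delta
        )[0]
    )


# ---------------------------------------------------------------------------
# model classes


def class_labels(max_cpt: int) -> list:
    """Model classes in increasing complexity: constant, linear, 1cpt, ..."""
    return ["constant", "linear"] + [f"{k}cpt" for k in range(1, max_cpt + 1)]


def class_dim(label: str, ignore=None) -> int:
    """Number of free coefficients M of a model class."""
    if label == "constant":
        return 1
    if label == "linear":
        return 2
    return int(label.removesuffix("cpt")) + 2


def _class_n_cpt(label: str) -> int:
    if label in ("constant", "linear"):
        return 0
    return int(label.removesuffix("cpt"))


@dataclass
class ClassFits:
    """Every fitted configuration of one model class, stacked.

    ``log_class_evidence`` is the log of the configuration-prior-weighted
    evidence sum (the mean over the uniform configuration prior); for the
    Monte Carlo mode it is the sampling estimate of that mean.  ``log_w``
    are normalized within-class configuration weights (proportional to
    evidence).  ``exact`` flags configurations whose rss is numerically
    zero; when any exist the evidence is formally infinite and downstream
    aggregation applies the sigma -> 0 limit.
    """

    label: str
    m: int
    pivots: Optional[np.ndarray]  # (ncfg, n_p); None for the constant class
    coef: np.ndarray  # (ncfg, m)
    rss: np.ndarray
    gram_logdet: np.ndarray
    gram: np.ndarray  # (ncfg, m, m)
    log_ev: np.ndarray
    log_class_evidence: float
    log_w: np.ndarray
    exact: np.ndarray  # bool per config
    mode: str  # "enum" or "mc"
    n_space: int  # size of the full configuration space
    mc_se_scaled: float = 0.0  # SE of the evidence mean / exp(mc_shift)
    mc_shift: float = 0.0

    @property
    def n_cfg(self) -> int:
        return len(self.rss)

    @property
    def any_exact(self) -> bool:
        return bool(self.exact.any())


def _finish_class(label, m, P, coef, rss, logdet, G, s, prior_margin, mode, n_space):
    delta = _prior_width(s, prior_margin)
    log_ev = _log_evidence_arr(rss, logdet, len(s), m, delta)
    exact = rss <= _exact_rss_tol(s)
    if exact.any():
        # sigma -> 0 limit: exact-fit configurations dominate; uniform over them
        log_w = np.full(len(rss), -np.inf)
        log_w[exact] = -math.log(int(exact.sum()))
        log_class_evidence = math.inf
    else:
        log_class_evidence = float(logsumexp(log_ev) - math.log(len(log_ev)))
        log_w = log_ev - logsumexp(log_ev)
    cf = ClassFits(
        label=label,
        m=m,
        pivots=P,
        coef=coef,
        rss=rss,
        gram_logdet=logdet,
        gram=G,
        log_ev=log_ev,
        log_class_evidence=log_class_evidence,
        log_w=log_w,
        exact=exact,
        mode=mode,
        n_space=n_space,
    )
    if mode == "mc" and not exact.any():
        shift = float(np.max(log_ev))
        ev = np.exp(log_ev - shift)
        cf.mc_shift = shift
        cf.mc_se_scaled = float(ev.std(ddof=1) / math.sqrt(len(ev))) if len(ev) > 1 else 0.0
    return cf


def _pivot_matrix_enum(n_cpt: int, s: TimeSeries) -> np.ndarray:
    interior = s.years[1:-1].astype(np.float64)
    if n_cpt == 0:
        mid = np.empty((1, 0))
    else:
        idx = np.array(list(combinations(range(len(interior)), n_cpt)), dtype=np.intp)
        mid = interior[idx]
    ncfg = len(mid)
    first = np.full((ncfg, 1), float(s.years[0]))
    last = np.full((ncfg, 1), float(s.years[-1]))
    return np.hstack([first, mid, last])


def _pivot_matrix_mc(n_cpt: int, s: TimeSeries, n_mc: int, rng) -> np.ndarray:
    interior = s.years[1:-1].astype(np.float64)
    # k smallest of iid uniforms per row = uniform random k-subset
    u = rng.random((n_mc, len(interior)))
    idx = np.sort(np.argpartition(u, n_cpt, axis=1)[:, :n_cpt], axis=1)
    mid = interior[idx]
    first = np.full((n_mc, 1), float(s.years[0]))
    last = np.full((n_mc, 1), float(s.years[-1]))
    return np.hstack([first, mid, last])


def fit_model_class(
    s: TimeSeries,
    label: str,
    prior_margin: float = 0.05,
    enum_limit: int = 100_000,
    n_mc: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    force_mode: Optional[str] = None,
) -> ClassFits:
    """Fit every configuration of one model class (or a Monte Carlo sample).

    Enumeration is exact and used whenever the configuration count is at
    most ``enum_limit`` (which covers up to two change points at N ~ 112);
    otherwise ``n_mc`` configurations are drawn uniformly with replacement
    and weighted by evidence, which is consistent for every configuration
    sum.
    """
    n_cpt = _class_n_cpt(label)
    if label != "constant" and n_cpt > len(s) - 3:
        raise ValueError(f"class {label} needs N >= {n_cpt + 3}, got N = {len(s)}")
    if label == "constant":
        coef, rss, logdet, G = _fit_constant(s)
        return _finish_class(
            label, 1, None, coef, rss, logdet, G, s, prior_margin, "enum", 1
        )
    n_space = n_configurations(n_cpt, len(s))
    mode = force_mode or ("enum" if n_space <= enum_limit else "mc")
    if mode == "enum":
        P = _pivot_matrix_enum(n_cpt, s)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        P = _pivot_matrix_mc(n_cpt, s, n_mc, rng)
    coef, rss, logdet, G = _fit_stack(P, s)
    m = n_cpt + 2
    return _finish_class(
        label, m, P, coef, rss, logdet, G, s, prior_margin, mode, n_space
    )


@dataclass
class MCSample:
    """Uniform-with-replacement configuration sample with evidence weights."""

    configs: list
    log_ev: np.ndarray
    weights: np.ndarray  # normalized, sum to 1
    log_class_evidence: float
    se_scaled: float
    shift: float


def sample_configs_mc(
    n_cpt: int, s: TimeSeries, n_mc: int, seed: int, prior_margin: float = 0.05
) -> MCSample:
    """Monte Carlo approximation of the configuration sum for one class.

    Draws ``n_mc`` configurations uniformly at random (with replacement)
    from the C(N-2, n_cpt) placements and attaches importance weights
    proportional to their evidence; the weighted mean of any per-
    configuration functional is then a consistent estimate of its exact
    enumerated (prior-weighted) value.
    """
    if n_cpt < 1:
        raise ValueError("sample_configs_mc requires n_cpt >= 1")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    cf = fit_model_class(
        s, f"{n_cpt}cpt", prior_margin=prior_margin, n_mc=n_mc, rng=rng,
        force_mode="mc",
    )
    configs = [
        PivotConfig(n_cpt, tuple(int(y) for y in row[1:-1])) for row in cf.pivots
    ]
    return MCSample(
        configs=configs,
        log_ev=cf.log_ev,
        weights=np.exp(cf.log_w),
        log_class_evidence=cf.log_class_evidence,
        se_scaled=cf.mc_se_scaled,
        shift=cf.mc_shift,
    )
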