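"""Model-class posteriors, model-averaged curves, credible bands, and fit quality.

Model classes (constant, linear, one change point, ... up to ``max_cpt``)
receive a uniform prior, and within a class every change-point configuration
receives a uniform prior.  The class evidence is therefore the mean of the
configuration evidences, and the posterior over classes is the normalized
class-evidence vector.  The final representation of a record is the average
over all configurations of all classes, weighted with their posterior
probabilities — a curve that is no longer a polygon.  Its derivative is the
corresponding weighted average of segment slopes and is the rate of change
in days/year (phenology; negative = advancing onset) or degrees C/year
(temperature; positive = warming).

Pointwise uncertainty combines, by the law of total variance, the within-
configuration posterior variance (multivariate Student, scale
``rss / (N - M - 2)`` through the basis projection) with the between-
configuration spread of the polygon means.  Credible bands at an arbitrary
level come from exact posterior sampling: draw (class, configuration) by
posterior weight, the noise scale from its inverse-chi-square marginal, and
the polygon vertices from the conditional Gaussian.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from . import core
from .core import ClassFits, class_labels
from .io import RunConfig, TimeSeries

__all__ = [
    "ModelPosterior",
    "FunctionEstimate",
    "FitQuality",
    "AnalysisResult",
    "model_posterior",
    "averaged_function",
    "averaged_derivative",
    "sample_posterior_draws",
    "model_efficiency",
    "analyze",
    "prior_sensitivity",
]

# configurations carrying less weight than this within their class are
# dropped from curve evaluation (not from the evidence); the truncated mass
# is renormalized and the induced error is far below plotting precision
_PRUNE_LOG_W = math.log(1e-14)


@dataclass(frozen=True)
class ModelPosterior:
    """Posterior over model classes, as printed in the probability tables."""

    classes: list
    log_class_evidence: np.ndarray
    probabilities: np.ndarray

    def as_dict(self) -> dict:
        return {c: float(p) for c, p in zip(self.classes, self.probabilities)}

    @property
    def best(self) -> str:
        return self.classes[int(np.argmax(self.probabilities))]


@dataclass(frozen=True)
class FunctionEstimate:
    """Model-averaged fit and rate of change on a year grid.

    ``sd`` / ``deriv_sd`` are pointwise standard errors of the estimated
    function and derivative (fit-function uncertainty, not predictive);
    credible bounds are filled by posterior sampling and are None until then.
    """

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    deriv_mean: np.ndarray
    deriv_sd: np.ndarray
    credible_lo: Optional[np.ndarray] = None
    credible_hi: Optional[np.ndarray] = None
    deriv_credible_lo: Optional[np.ndarray] = None
    deriv_credible_hi: Optional[np.ndarray] = None


@dataclass(frozen=True)
class FitQuality:
    """Model efficiency ME = (SS_tot - SS_res) / SS_tot."""

    ss_tot: float
    ss_res: float
    me: float


@dataclass(frozen=True)
class AnalysisResult:
    series: TimeSeries
    config: RunConfig
    posterior: ModelPosterior
    estimate: FunctionEstimate
    quality: Optional[FitQuality]
    #: per-class stacked configuration fits (label -> ClassFits)
    class_fits: Optional[dict] = None

    def cpt_location(self, label: str = "1cpt") -> float:
        """Posterior-weight-weighted mean change-point year within a class."""
        cf = self.class_fits[label]
        w = np.exp(cf.log_w)
        # mean over interior pivots, weighted by configuration probability
        return float((w[:, None] * cf.pivots[:, 1:-1]).sum() / w.sum())


# ---------------------------------------------------------------------------
# class fitting and posterior


def _fit_all_classes(s: TimeSeries, cfg: RunConfig) -> dict:
    if cfg.max_cpt > len(s) - 3:
        raise ValueError(
            f"max_cpt = {cfg.max_cpt} needs N >= {cfg.max_cpt + 3}, got N = {len(s)}"
        )
    rng_mc = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[0])
    fits = {}
    for label in class_labels(cfg.max_cpt):
        fits[label] = core.fit_model_class(
            s,
            label,
            prior_margin=cfg.prior_margin,
            enum_limit=cfg.enum_limit,
            n_mc=cfg.n_mc,
            rng=rng_mc,
        )
    return fits


def _posterior_from_fits(fits: dict) -> ModelPosterior:
    labels = list(fits)
    log_ev = np.array([fits[c].log_class_evidence for c in labels])
    if np.isinf(log_ev).any():
        # exact-fit limit: probability 1 to the lowest-dimension class that
        # contains a configuration fitting the data exactly
        exact_classes = [c for c in labels if fits[c].any_exact]
        best = min(exact_classes, key=lambda c: fits[c].m)
        prob = np.array([1.0 if c == best else 0.0 for c in labels])
    else:
        prob = np.exp(log_ev - logsumexp(log_ev))
        prob /= prob.sum()
    return ModelPosterior(classes=labels, log_class_evidence=log_ev, probabilities=prob)


def model_posterior(s: TimeSeries, cfg: RunConfig = RunConfig()) -> ModelPosterior:
    """Posterior probabilities of the model classes for one record.

    Uniform prior over classes and, within a class, over the C(N-2, n_cpt)
    change-point placements; the class evidence is the mean of the
    configuration evidences (enumerated exactly, or Monte Carlo estimated
    for spaces larger than ``cfg.enum_limit``).
    """
    return _posterior_from_fits(_fit_all_classes(s, cfg))


# ---------------------------------------------------------------------------
# model-averaged curves


def _pruned(cf: ClassFits):
    """Indices of configurations that carry non-negligible class weight."""
    keep = np.flatnonzero(cf.log_w > _PRUNE_LOG_W)
    w = np.exp(cf.log_w[keep])
    return keep, w / w.sum()


def _class_curves(cf: ClassFits, s: TimeSeries, t: np.ndarray, need_var: bool):
    """Per-configuration polygon values, slopes and within-variances on t.

    Returns (keep, w, vals, slopes, vfit, vslope) with vals/... of shape
    (n_kept, T).  Within-variances are the Student posterior variances of
    the function value / slope, scale rss / (N - M - 2) through the basis
    projection; if the variance degrees of freedom are not positive (only
    possible for records shorter than about six years) they are estimated
    from coefficient draws instead.
    """
    keep, w = _pruned(cf)
    n_obs = len(s)
    if cf.pivots is None:  # constant class
        vals = np.repeat(cf.coef[keep], len(t), axis=1)
        slopes = np.zeros_like(vals)
        if not need_var:
            return keep, w, vals, slopes, None, None
        dof = n_obs - 1 - 2
        if dof > 0:
            sig2 = cf.rss[keep] / dof
        else:
            sig2 = _sig2_by_draws(cf, keep, n_obs)
        vfit = np.repeat((sig2 / n_obs)[:, None], len(t), axis=1)
        return keep, w, vals, slopes, vfit, np.zeros_like(vfit)
    P = cf.pivots[keep]
    coef = cf.coef[keep]
    H = core._basis_stack(P, t)
    vals = np.einsum("ctm,cm->ct", H, coef)
    slopes = core._slope_stack(P, coef, t)
    if not need_var:
        return keep, w, vals, slopes, None, None
    dof = n_obs - cf.m - 2
    if dof > 0:
        sig2 = cf.rss[keep] / dof
    else:
        warnings.warn(
            f"class {cf.label}: too few residual degrees of freedom for the "
            "closed-form posterior variance; using draw-based estimate",
            stacklevel=3,
        )
        sig2 = _sig2_by_draws(cf, keep, n_obs)
    Ginv = np.linalg.inv(cf.gram[keep])
    D = core._slope_functional_stack(P, t)
    vfit = np.einsum("ctm,cml,ctl->ct", H, Ginv, H) * sig2[:, None]
    vslope = np.einsum("ctm,cml,ctl->ct", D, Ginv, D) * sig2[:, None]
    return keep, w, vals, slopes, vfit, vslope


def _sig2_by_draws(cf: ClassFits, keep, n_obs, n=4096, seed=0):
    # heavy-tailed when N - M <= 2; a trimmed draw-based scale is used
    rng = np.random.default_rng(seed)
    nu = max(n_obs - cf.m, 1)
    out = np.empty(len(keep))
    for i, j in enumerate(keep):
        draws = cf.rss[j] / rng.chisquare(nu, n)
        out[i] = float(np.mean(np.sort(draws)[: int(0.98 * n)]))
    return out


def _flat_weights(fits: dict, posterior: ModelPosterior):
    """(label, keep, joint weight) for every retained configuration."""
    entries = []
    for label, p_class in zip(posterior.classes, posterior.probabilities):
        if p_class <= 0.0:
            continue
        cf = fits[label]
        keep, w = _pruned(cf)
        entries.append((label, keep, p_class * w))
    return entries


def _estimate_from_fits(
    fits: dict, posterior: ModelPosterior, s: TimeSeries, t: np.ndarray
) -> FunctionEstimate:
    exact = any(fits[c].any_exact for c in posterior.classes)
    mean = np.zeros(len(t))
    dmean = np.zeros(len(t))
    m2 = np.zeros(len(t))
    dm2 = np.zeros(len(t))
    within = np.zeros(len(t))
    dwithin = np.zeros(len(t))
    for label, p_class in zip(posterior.classes, posterior.probabilities):
        if p_class <= 0.0:
            continue
        cf = fits[label]
        _, w, vals, slopes, vfit, vslope = _class_curves(
            cf, s, t, need_var=not exact
        )
        wc = p_class * w
        mean += wc @ vals
        dmean += wc @ slopes
        m2 += wc @ (vals**2)
        dm2 += wc @ (slopes**2)
        if not exact:
            within += wc @ vfit
            dwithin += wc @ vslope
    between = np.maximum(m2 - mean**2, 0.0)
    dbetween = np.maximum(dm2 - dmean**2, 0.0)
    return FunctionEstimate(
        grid=t,
        mean=mean,
        sd=np.sqrt(within + between),
        deriv_mean=dmean,
        deriv_sd=np.sqrt(dwithin + dbetween),
    )


def averaged_function(s: TimeSeries, cfg: RunConfig = RunConfig()) -> FunctionEstimate:
    """Model-averaged fit curve with pointwise standard errors.

    mean(t) = sum over classes and configurations of the posterior-weighted
    least-squares polygons; the standard error combines within-configuration
    posterior variance and between-configuration spread.
    """
    fits = _fit_all_classes(s, cfg)
    posterior = _posterior_from_fits(fits)
    return _estimate_from_fits(fits, posterior, s, cfg.grid_for(s))


def averaged_derivative(s: TimeSeries, cfg: RunConfig = RunConfig()) -> FunctionEstimate:
    """Model-averaged rate of change (the derivative of the fit curve).

    Per configuration the derivative is the piecewise-constant segment
    slope (left-slope convention at pivots); averaging over configurations
    yields an effectively smooth rate curve.
    """
    return averaged_function(s, cfg)


# ---------------------------------------------------------------------------
# posterior draws and credible bands


def _draw_bands(
    fits: dict,
    posterior: ModelPosterior,
    s: TimeSeries,
    t: np.ndarray,
    n_draws: int,
    level: float,
    rng: np.random.Generator,
):
    alpha = 0.5 * (1.0 - level)
    exact = any(fits[c].any_exact for c in posterior.classes)
    if exact:
        est = _estimate_from_fits(fits, posterior, s, t)
        return est.mean.copy(), est.mean.copy(), est.deriv_mean.copy(), est.deriv_mean.copy()
    entries = _flat_weights(fits, posterior)
    labels = [e[0] for e in entries]
    w_all = np.concatenate([e[2] for e in entries])
    w_all = w_all / w_all.sum()
    counts = rng.multinomial(n_draws, w_all)
    bounds = np.cumsum([0] + [len(e[2]) for e in entries])
    n_obs = len(s)
    fit_draws = np.empty((n_draws, len(t)))
    der_draws = np.empty((n_draws, len(t)))
    pos = 0
    for bi, (label, keep, _) in enumerate(entries):
        cf = fits[label]
        sub = counts[bounds[bi] : bounds[bi + 1]]
        nu = n_obs - cf.m
        for ci in np.flatnonzero(sub):
            k = int(sub[ci])
            j = keep[ci]
            sig = np.sqrt(cf.rss[j] / rng.chisquare(nu, k))
            if cf.pivots is None:
                f = cf.coef[j, 0] + sig * rng.standard_normal(k) / math.sqrt(n_obs)
                fit_draws[pos : pos + k] = f[:, None]
                der_draws[pos : pos + k] = 0.0
            else:
                L = np.linalg.cholesky(cf.gram[j])
                z = rng.standard_normal((cf.m, k))
                # cov(coef) = sigma^2 G^-1 ; G = L L' -> coef = fhat + sigma L'^-1 z
                devs = np.linalg.solve(L.T, z)  # (m, k)
                f = cf.coef[j][None, :] + (sig[:, None] * devs.T)
                P1 = cf.pivots[j][None, :]
                H = core._basis_stack(P1, t)[0]  # (T, m)
                D = core._slope_functional_stack(P1, t)[0]
                fit_draws[pos : pos + k] = f @ H.T
                der_draws[pos : pos + k] = f @ D.T
            pos += k
    qs = np.array([alpha, 1.0 - alpha])
    flo, fhi = np.quantile(fit_draws, qs, axis=0)
    dlo, dhi = np.quantile(der_draws, qs, axis=0)
    return flo, fhi, dlo, dhi


def sample_posterior_draws(s: TimeSeries, cfg: RunConfig = RunConfig()) -> FunctionEstimate:
    """Full estimate with sampled central credible bands for fit and rate.

    Sampling is exact (no Markov chain): a (class, configuration) pair is
    drawn by posterior weight, the noise variance from its scaled
    inverse-chi-square marginal, and the polygon vertices from the
    conditional Gaussian; the polygon and its slopes are then evaluated on
    the grid, and pointwise central quantiles at ``cfg.credible_level``
    form the band.  Deterministic under ``cfg.seed``.
    """
    fits = _fit_all_classes(s, cfg)
    posterior = _posterior_from_fits(fits)
    t = cfg.grid_for(s)
    est = _estimate_from_fits(fits, posterior, s, t)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    flo, fhi, dlo, dhi = _draw_bands(
        fits, posterior, s, t, cfg.n_draws, cfg.credible_level, rng
    )
    return FunctionEstimate(
        grid=t,
        mean=est.mean,
        sd=est.sd,
        deriv_mean=est.deriv_mean,
        deriv_sd=est.deriv_sd,
        credible_lo=flo,
        credible_hi=fhi,
        deriv_credible_lo=dlo,
        deriv_credible_hi=dhi,
    )


# ---------------------------------------------------------------------------
# fit quality


def model_efficiency(s: TimeSeries, fit: FunctionEstimate) -> FitQuality:
    """ME = (SS_tot - SS_res) / SS_tot of the model-averaged fit.

    SS_tot is the sum of squared deviations of the observations from their
    mean; SS_res the sum of squared residuals of the averaged fit at the
    observation years (the fit grid must cover them all).
    """
    idx = np.searchsorted(fit.grid, s.years.astype(np.float64))
    ok = (idx < len(fit.grid)) & np.isclose(
        fit.grid[np.minimum(idx, len(fit.grid) - 1)], s.years
    )
    if not ok.all():
        raise ValueError("fit grid does not cover all observation years")
    ss_tot = float(((s.values - s.values.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("degenerate series: zero total sum of squares")
    resid = s.values - fit.mean[idx]
    ss_res = float((resid**2).sum())
    return FitQuality(ss_tot=ss_tot, ss_res=ss_res, me=(ss_tot - ss_res) / ss_tot)


# ---------------------------------------------------------------------------
# one-call pipeline


def analyze(s: TimeSeries, cfg: RunConfig = RunConfig(), bands: bool = True) -> AnalysisResult:
    """Run the full pipeline once: posterior, averaged curves, bands, ME.

    Classes are fitted a single time and shared by every output, so this is
    the entry point the CLI and any replicated experiment should use.
    """
    if cfg.end_year is not None:
        from .io import truncate_series

        s = truncate_series(s, cfg.end_year)
    fits = _fit_all_classes(s, cfg)
    posterior = _posterior_from_fits(fits)
    t = cfg.grid_for(s)
    est = _estimate_from_fits(fits, posterior, s, t)
    if bands:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
        flo, fhi, dlo, dhi = _draw_bands(
            fits, posterior, s, t, cfg.n_draws, cfg.credible_level, rng
        )
        est = FunctionEstimate(
            grid=t,
            mean=est.mean,
            sd=est.sd,
            deriv_mean=est.deriv_mean,
            deriv_sd=est.deriv_sd,
            credible_lo=flo,
            credible_hi=fhi,
            deriv_credible_lo=dlo,
            deriv_credible_hi=dhi,
        )
    quality = None
    obs = s.years.astype(np.float64)
    if np.all(np.isin(obs, t)) and s.value_range > 0:
        quality = model_efficiency(s, est)
    return AnalysisResult(
        series=s,
        config=cfg,
        posterior=posterior,
        estimate=est,
        quality=quality,
        class_fits=fits,
    )


def prior_sensitivity(
    s: TimeSeries, cfg: RunConfig = RunConfig(), margins=(0.0, 0.05, 0.10)
) -> dict:
    """Class probabilities under alternative coefficient-prior margins.

    The prior width is (1 + 2*margin) times the data range; the margin acts
    only through the per-dimension Ockham penalty, so this reports how much
    the class probabilities move when the margin is varied.
    """
    from dataclasses import replace

    out = {}
    for m in margins:
        post = model_posterior(s, replace(cfg, prior_margin=float(m)))
        out[float(m)] = post.as_dict()
    return out
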