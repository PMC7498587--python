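"""Trend priors: vague, or built from a climate-model ensemble.

The informative prior mirrors how CMIP5-style output is condensed into a
"first guess" for the observational trend: a GLS regression with AR(1)
errors extracts a trend from each model run's regional-mean series,
ensemble members are averaged within each model (so multi-member models get
no extra weight), and the across-model mean and sample variance become a
normal prior for the trend coefficient.  The vague alternative is
N(0, 100), effectively flat over any plausible trend.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationFailureError, InsufficientDataError, InvalidConfigurationError
from .fields import calendar_months
from .summarize import MONTHS_PER_YEAR

LOG_PER_MONTH = "log-per-month"
PERCENT_PER_YEAR = "percent-per-year"
_SCALES = (LOG_PER_MONTH, PERCENT_PER_YEAR)

#: variance floor (percent-per-year scale) applied to degenerate ensembles
VARIANCE_FLOOR_PCT = 1e-6
_DEGENERATE_PCT = 1e-8


@dataclass(frozen=True)
class TrendPrior:
    """Normal prior for the trend coefficient, with an explicit unit scale."""

    mean: float
    variance: float
    unit_scale: str
    provenance: str  # "vague" | "ensemble"
    n_models: int = 0

    def __post_init__(self) -> None:
        if self.unit_scale not in _SCALES:
            raise InvalidConfigurationError(f"unknown unit scale {self.unit_scale!r}")
        if self.variance <= 0:
            raise InvalidConfigurationError("prior variance must be positive")


def vague_prior(unit_scale: str = PERCENT_PER_YEAR) -> TrendPrior:
    """The no-knowledge prior: mean 0, variance 100."""
    return TrendPrior(mean=0.0, variance=100.0, unit_scale=unit_scale, provenance="vague", n_models=0)


def _dlog_dpct(mean_pct: float) -> float:
    # derivative of ln(1 + m/100)/12 w.r.t. m
    return 1.0 / (MONTHS_PER_YEAR * 100.0 * (1.0 + mean_pct / 100.0))


def convert_prior_units(prior: TrendPrior, target_scale: str) -> TrendPrior:
    """Map (mean, variance) between % year^-1 and log month^-1 scales.

    Means map exactly through the monotone trend conversion; variances by
    the delta method (first-order), which is exact in the round trip.
    """
    if target_scale not in _SCALES:
        raise InvalidConfigurationError(f"unknown unit scale {target_scale!r}")
    if prior.unit_scale == target_scale:
        return prior
    if prior.unit_scale == PERCENT_PER_YEAR:
        if prior.mean <= -100.0:
            raise ValueError("percent-per-year prior mean must exceed -100")
        d = _dlog_dpct(prior.mean)
        mean = np.log1p(prior.mean / 100.0) / MONTHS_PER_YEAR
        return replace(prior, mean=float(mean), variance=float(prior.variance * d * d), unit_scale=target_scale)
    d = MONTHS_PER_YEAR * 100.0 * np.exp(MONTHS_PER_YEAR * prior.mean)
    mean = (np.exp(MONTHS_PER_YEAR * prior.mean) - 1.0) * 100.0
    return replace(prior, mean=float(mean), variance=float(prior.variance * d * d), unit_scale=target_scale)


def _gls_design(n: int, months: np.ndarray | None, peak_month: int | None) -> np.ndarray:
    t = np.arange(n, dtype=float)
    cols = [np.ones(n), t]
    if peak_month is not None:
        if months is None:
            raise InvalidConfigurationError("seasonal covariate needs calendar months")
        cols.append(np.cos(2.0 * np.pi * (months - peak_month) / 12.0))
    return np.column_stack(cols)


def _prais_winsten(X: np.ndarray, y: np.ndarray, rho: float) -> np.ndarray:
    """GLS estimate under AR(1) errors by whitening, keeping the first row."""
    Xs = X.copy()
    ys = y.copy()
    c = np.sqrt(1.0 - rho * rho)
    Xs[0] *= c
    ys[0] *= c
    Xs[1:] -= rho * X[:-1]
    ys[1:] -= rho * y[:-1]
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    return beta


def fit_gls_ar1_trend(
    series: np.ndarray,
    start_month: tuple[int, int] | None = None,
    seasonal: bool = True,
    peak_month: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float, float]:
    """Linear trend (log month^-1) by iterated feasible GLS with AR(1) errors.

    Covariates: intercept, time, and (by default) a fixed-phase annual
    cosine whose peak is ``peak_month`` (taken from the series climatology
    when not given).  rho is re-estimated from residual lag-1
    autocorrelation each iteration until it settles to ``tol``.

    Returns ``(slope, rho_hat)``.
    """
    series = np.asarray(series, dtype=float).ravel()
    finite = np.isfinite(series)
    if finite.sum() < 24:
        raise InsufficientDataError("need at least 24 non-missing months for a trend fit")
    first, last = np.nonzero(finite)[0][[0, -1]]
    if not finite[first : last + 1].all():
        raise InsufficientDataError("interior missing months are not supported in the GLS trend fit")
    y = series[first : last + 1]
    n = y.size

    months = None
    pk = None
    if seasonal:
        if start_month is None:
            start_month = (2000, 1)
        months = calendar_months(start_month, series.size)[first : last + 1]
        if peak_month is None:
            clim = np.array([y[months == m].mean() for m in range(1, 13)])
            pk = int(np.argmax(clim)) + 1
        else:
            pk = int(peak_month)
    X = _gls_design(n, months, pk)
    # time column offset by the leading trim so slopes refer to the original index
    X[:, 1] += first

    rho = 0.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(max_iter):
        resid = y - X @ beta
        denom = float(resid @ resid)
        # a numerically perfect fit has no autocorrelation to estimate
        degenerate = denom <= 1e-24 * max(float(y @ y), 1.0)
        rho_new = float(resid[1:] @ resid[:-1] / denom) if not degenerate else 0.0
        if abs(rho_new) >= 1.0:
            warnings.warn("estimated AR(1) coefficient outside (-1, 1); clipped to +/-0.99")
            rho_new = float(np.clip(rho_new, -0.99, 0.99))
        beta = _prais_winsten(X, y, rho_new)
        if abs(rho_new - rho) < tol:
            return float(beta[1]), rho_new
        rho = rho_new
    raise EstimationFailureError(
        f"AR(1) GLS did not converge in {max_iter} iterations", last_iterate=(float(beta[1]), rho)
    )


def average_ensembles(run_trends: Iterable[tuple[str, str, float]]) -> dict[str, float]:
    """Mean trend per model over its ensemble members (unweighted)."""
    by_model: dict[str, list[float]] = defaultdict(list)
    n = 0
    for model_id, _ensemble_id, slope in run_trends:
        by_model[model_id].append(float(slope))
        n += 1
    if n == 0:
        raise InvalidConfigurationError("no run trends supplied")
    return {m: float(np.mean(v)) for m, v in by_model.items()}


def build_multimodel_prior(model_trends: Mapping[str, float], unit_scale: str) -> TrendPrior:
    """Across-model mean and sample variance (ddof=1) as a normal prior."""
    vals = np.array(list(model_trends.values()), dtype=float)
    if vals.size < 2:
        raise InvalidConfigurationError("at least two models are required for a prior variance")
    mean = float(vals.mean())
    var = float(vals.var(ddof=1))
    # degeneracy check on the percent-per-year scale regardless of input scale
    scale_to_pct = 1.0 if unit_scale == PERCENT_PER_YEAR else (MONTHS_PER_YEAR * 100.0 * np.exp(MONTHS_PER_YEAR * mean)) ** 2
    if var * scale_to_pct < _DEGENERATE_PCT:
        warnings.warn("degenerate ensemble spread; prior variance floored")
        var = VARIANCE_FLOOR_PCT / scale_to_pct
    return TrendPrior(mean=mean, variance=var, unit_scale=unit_scale, provenance="ensemble", n_models=vals.size)


def build_region_priors(
    runs: Sequence["ClimateRunSeries"],
    seasonal: bool = True,
) -> dict[int, TrendPrior]:
    """Full prior pipeline: per-run GLS trends -> ensemble means -> prior, per region."""
    by_region: dict[int, list] = defaultdict(list)
    for run in runs:
        by_region[run.region_id].append(run)
    priors: dict[int, TrendPrior] = {}
    for region_id, region_runs in sorted(by_region.items()):
        trends = [
            (r.model_id, r.ensemble_id, fit_gls_ar1_trend(r.series, start_month=r.start_month, seasonal=seasonal)[0])
            for r in region_runs
        ]
        priors[region_id] = build_multimodel_prior(average_ensembles(trends), unit_scale=LOG_PER_MONTH)
    return priors


def prior_table(priors: Mapping[int, TrendPrior]) -> pd.DataFrame:
    """Per-region prior table on the reporting (% year^-1) scale."""
    rows = []
    for region_id, prior in sorted(priors.items()):
        p = convert_prior_units(prior, PERCENT_PER_YEAR)
        rows.append(
            {
                "region_id": region_id,
                "prior_mean_pct_yr": p.mean,
                "prior_var": p.variance,
                "n_models": p.n_models,
                "provenance": p.provenance,
            }
        )
    return pd.DataFrame(rows)
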