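"""Hierarchical Bayesian spatio-temporal trend model, fitted per region.

Data level: Z_{n,t} = O_{n,t} + eps_{n,t} with iid Gaussian measurement
error (nugget).  Process level: O_{n,t} = x_t' beta + w_{n,t}, where the
covariates are an intercept, centered time (the trend) and an annual
cosine with phase fixed at the climatological chlorophyll peak, and w is
an AR(1)-in-time process whose innovations carry an exponential spatial
correlation exp(-d / lambda) in great-circle distance (lambda fixed,
default 500 km so correlation is ~0.05 by 1,500 km).

The trend coefficient carries a normal prior — vague N(0, 100 (%/yr)^2)
or built from a climate-model ensemble — while the other levels get
standard weakly informative hyperpriors.  Fitting is by Gibbs sampling:
conjugate draws for the coefficients and variances, joint
forward-filter/backward-sample updates for w, griddy Gibbs for rho, and
conditional-normal imputation of missing observations each sweep.  For
large regions an optional reduced-rank (predictive-process) approximation
places knots on a regular sub-grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla

from . import _kernels
from .errors import (
    DegenerateGeometryError,
    DivergenceError,
    InsufficientDataError,
    InvalidConfigurationError,
)
from .fields import ChlField, calendar_months
from .priors import LOG_PER_MONTH, TrendPrior, convert_prior_units, vague_prior
from .regions import NO_REGION, RegionMask, pairwise_distances_km


def spatial_correlation(distance_km, decay_km: float):
    """Exponential spatial correlation exp(-d / decay)."""
    if decay_km <= 0:
        raise ValueError("decay length must be positive")
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-d / decay_km)
    return float(out) if np.isscalar(distance_km) else out


@dataclass
class STModelConfig:
    """Sampler settings and hyperpriors for one regional fit.

    ``n_iterations`` counts post-burn-in draws.  ``knots`` switches on the
    reduced-rank approximation when set.  ``sample_process``/
    ``fixed_nugget_variance`` exist to run the model in its conjugate
    linear-regression limit (process disabled, known nugget).
    """

    trend_prior: TrendPrior = field(default_factory=vague_prior)
    spatial_decay_km: float = 500.0
    n_iterations: int = 5000
    n_burnin: int = 1000
    seed: int = 0
    intercept_prior_var: float = 1e4
    seasonal_prior_var: float = 1e4
    nugget_ig_shape: float = 0.01
    nugget_ig_scale: float = 0.01
    process_ig_shape: float = 0.01
    process_ig_scale: float = 0.01
    knots: Optional[int] = None
    sample_process: bool = True
    fixed_nugget_variance: Optional[float] = None
    mh_step_logvar: float = 0.3
    mh_step_atanh_rho: float = 0.2

    def __post_init__(self) -> None:
        if self.n_iterations < 1000:
            raise InvalidConfigurationError("n_iterations must be at least 1,000")
        if self.n_burnin < 0:
            raise InvalidConfigurationError("n_burnin must be non-negative")
        if self.spatial_decay_km <= 0:
            raise InvalidConfigurationError("spatial_decay_km must be positive")
        if min(self.intercept_prior_var, self.seasonal_prior_var) <= 0:
            raise InvalidConfigurationError("hyperprior variances must be positive")

    def echo(self) -> dict:
        p = self.trend_prior
        return {
            "trend_prior": {
                "mean": p.mean,
                "variance": p.variance,
                "unit_scale": p.unit_scale,
                "provenance": p.provenance,
                "n_models": p.n_models,
            },
            "spatial_decay_km": self.spatial_decay_km,
            "n_iterations": self.n_iterations,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
            "knots": self.knots,
            "sample_process": self.sample_process,
            "fixed_nugget_variance": self.fixed_nugget_variance,
        }


@dataclass
class DesignMatrix:
    """Shared time-design for every cell of a region.

    Columns: intercept, centered time (months), annual cosine with phase
    fixed so the crest lands on ``peak_month``.  Rows conceptually index
    (cell, month); since the covariates do not vary across cells only the
    T x 3 time block is stored.
    """

    x_time: np.ndarray  # (T, 3)
    peak_month: int
    start_month: tuple[int, int]
    region_id: int
    n_cells: int

    @property
    def n_months(self) -> int:
        return self.x_time.shape[0]

    def full_matrix(self) -> np.ndarray:
        """The stacked (cell x month, 3) design, cells varying slowest."""
        return np.tile(self.x_time, (self.n_cells, 1))


def build_design(field: ChlField, mask: RegionMask, region_id: int, peak_month: int) -> DesignMatrix:
    """Design matrix for one region: intercept, centered time, fixed-phase cosine."""
    if not 1 <= int(peak_month) <= 12:
        raise InvalidConfigurationError(f"peak month {peak_month} not in 1..12")
    rows, cols = mask.cells_of(region_id)  # raises KeyError for unknown region
    if rows.size == 0:
        raise KeyError(f"region {region_id} has no cells")
    T = field.n_months
    t = np.arange(T, dtype=float)
    t_centered = t - (T - 1) / 2.0
    months = calendar_months(field.start_month, T)
    seasonal = np.cos(2.0 * np.pi * (months - int(peak_month)) / 12.0)
    X = np.column_stack([np.ones(T), t_centered, seasonal])
    return DesignMatrix(
        x_time=X,
        peak_month=int(peak_month),
        start_month=field.start_month,
        region_id=region_id,
        n_cells=int(rows.size),
    )


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws for one regional fit."""

    beta: np.ndarray  # (n_draws, 3): intercept, trend (log/month), seasonal
    sigma2_nugget: np.ndarray
    sigma2_process: np.ndarray
    rho: np.ndarray
    region_id: int
    seed: int
    config: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def trend_draws(self) -> np.ndarray:
        """Trend coefficient draws, log-chl per month."""
        return self.beta[:, 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_intercept": self.beta[:, 0],
                "beta_trend": self.beta[:, 1],
                "beta_seasonal": self.beta[:, 2],
                "sigma2_nugget": self.sigma2_nugget,
                "sigma2_process": self.sigma2_process,
                "rho": self.rho,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _select_knots(lats: np.ndarray, lons: np.ndarray, n_knots: int) -> np.ndarray:
    """Indices of ~n_knots cells spread on a regular sub-grid of the region."""
    order = np.lexsort((lons, lats))
    stride = max(1, int(round(lats.size / n_knots)))
    return order[::stride][:n_knots]


def _mode_basis(S_knots: np.ndarray, A: np.ndarray):
    """Basis V with V V' = S_knots and V' A'A V diagonal (eigenvalues mu).

    In this basis the latent modes have identity innovation covariance and
    decoupled scalar observations, which is what lets the FFBS run as
    independent scalar Kalman filters.
    """
    evals, evecs = np.linalg.eigh(S_knots)
    if evals.min() <= 0:
        raise DegenerateGeometryError("knot correlation matrix is not positive definite")
    V0 = evecs * np.sqrt(evals)
    M = V0.T @ (A.T @ A) @ V0
    mu, Q = np.linalg.eigh((M + M.T) / 2.0)
    mu = np.clip(mu, 0.0, None)
    V = V0 @ Q
    return V, mu


def _process_log_prior(sig2_w: float, rho: float, config: STModelConfig) -> float:
    """Log prior of (sigma2_w, rho) plus the (log, atanh) transform Jacobians.

    sigma2_w ~ inverse-gamma(shape, scale), rho ~ uniform(-1, 1); the
    Jacobian terms make the Metropolis walk on (log sigma2_w, atanh rho)
    target the right density.
    """
    a, b = config.process_ig_shape, config.process_ig_scale
    return float(-a * np.log(sig2_w) - b / sig2_w + np.log1p(-rho * rho))


def fit_st_model(
    field: ChlField,
    mask: RegionMask,
    region_id: int,
    design: DesignMatrix,
    config: STModelConfig,
) -> PosteriorSamples:
    """Gibbs-sample the regional spatio-temporal model.

    Returns ``config.n_iterations`` post-burn-in draws; bit-reproducible
    given (data, config, seed).
    """
    rows, cols = mask.cells_of(region_id)
    N = rows.size
    T = field.n_months
    if N < 4:
        raise InsufficientDataError(f"region {region_id} has {N} cells; need at least 4")
    if T < 24:
        raise InsufficientDataError("need at least 24 months")
    Z = field.values[rows, cols, :].astype(float)  # (N, T)
    obs = np.isfinite(Z)
    if not obs.any(axis=0).all():
        bad = int(np.nonzero(~obs.any(axis=0))[0][0])
        raise InsufficientDataError(f"month index {bad} has no data in region {region_id}")

    X = design.x_time  # (T, 3)
    XtX = X.T @ X
    prior = convert_prior_units(config.trend_prior, LOG_PER_MONTH)
    prior_prec = np.diag([1.0 / config.intercept_prior_var, 1.0 / prior.variance, 1.0 / config.seasonal_prior_var])
    prior_mean = np.array([0.0, prior.mean, 0.0])

    # spatial structure (lambda fixed) -----------------------------------
    lats, lons = mask.lat_centers[rows], mask.lon_centers[cols]
    if config.sample_process:
        dist = pairwise_distances_km(lats, lons)
        off = dist[~np.eye(N, dtype=bool)]
        if off.size and off.min() <= 0:
            raise DegenerateGeometryError("duplicate cell coordinates in region")
        S = np.exp(-dist / config.spatial_decay_km)
        if config.knots is not None and config.knots < N:
            idx = _select_knots(lats, lons, config.knots)
            S_knots = S[np.ix_(idx, idx)]
            A = np.linalg.solve(S_knots, S[:, idx].T).T  # C(cells,knots) C(knots,knots)^-1
        else:
            S_knots = S
            A = np.eye(N)
        V, mu = _mode_basis(S_knots, A)
        AV = A @ V
        AVt = AV.T
        m_modes = V.shape[0]
    else:
        AV = AVt = None
        mu = None
        m_modes = 0

    rng = np.random.default_rng(config.seed)

    # initialization ------------------------------------------------------
    Zc = Z.copy()
    col_mean = np.where(obs.any(axis=0), np.nanmean(np.where(obs, Z, np.nan), axis=0), 0.0)
    Zc[~obs] = np.broadcast_to(col_mean, (N, T))[~obs]
    ybar = Zc.mean(axis=0)
    beta, *_ = np.linalg.lstsq(X, ybar, rcond=None)
    resid0 = Zc - X @ beta
    s2 = float(np.var(resid0))
    sig2_eps = config.fixed_nugget_variance if config.fixed_nugget_variance is not None else max(s2 / 2, 1e-8)
    sig2_w = max(s2 / 2, 1e-8)
    rho = 0.0
    w_obs = np.zeros((N, T))

    n_total = config.n_burnin + config.n_iterations
    out_beta = np.empty((config.n_iterations, 3))
    out_s2e = np.empty(config.n_iterations)
    out_s2w = np.empty(config.n_iterations)
    out_rho = np.empty(config.n_iterations)

    n_missing = int((~obs).sum())
    n_accept = 0
    step_logvar = config.mh_step_logvar
    step_rho = config.mh_step_atanh_rho
    for sweep in range(n_total):
        mean_surface = (X @ beta)[None, :] + w_obs
        # (v) impute missing observations from their conditional normal
        if n_missing:
            Zc[~obs] = mean_surface[~obs] + np.sqrt(sig2_eps) * rng.standard_normal(n_missing)

        # (i) beta | rest — conjugate normal
        Y = Zc - w_obs
        P = N * XtX / sig2_eps + prior_prec
        b = X.T @ Y.sum(axis=0) / sig2_eps + prior_prec @ prior_mean
        L = np.linalg.cholesky(P)
        mean_beta = sla.cho_solve((L, True), b)
        beta = mean_beta + sla.solve_triangular(L, rng.standard_normal(3), lower=True, trans="T")

        if config.sample_process:
            resid = Zc - (X @ beta)[None, :]
            ytilde = AVt @ resid
            np.divide(ytilde, mu[:, None], out=ytilde, where=mu[:, None] > 0)

            # (iii)+(iv) joint Metropolis on (sigma2_w, rho) against the
            # w-marginalized likelihood, then (ii) FFBS for w.  Collapsing w
            # out is what lets these parameters move: their full
            # conditionals given w are so sharp that a pure Gibbs scan
            # random-walks and never leaves the neighbourhood of its start.
            loglik_cur = _kernels.ar1_noise_loglik(ytilde, mu, rho, sig2_w, sig2_eps) + _process_log_prior(
                sig2_w, rho, config
            )
            prop_logvar = np.log(sig2_w) + step_logvar * rng.standard_normal()
            prop_atanh = np.arctanh(rho) + step_rho * rng.standard_normal()
            sig2_w_p = float(np.exp(prop_logvar))
            rho_p = float(np.tanh(prop_atanh))
            loglik_prop = _kernels.ar1_noise_loglik(ytilde, mu, rho_p, sig2_w_p, sig2_eps) + _process_log_prior(
                sig2_w_p, rho_p, config
            )
            accept = np.log(rng.random()) < loglik_prop - loglik_cur
            if accept:
                sig2_w, rho = sig2_w_p, rho_p
                n_accept += 1
            if sweep < config.n_burnin:  # Robbins-Monro tuning toward ~30% acceptance
                adapt = 1.0 / np.sqrt(sweep + 1.0)
                scale_step = np.exp(adapt * ((1.0 if accept else 0.0) - 0.3))
                step_logvar *= scale_step
                step_rho *= scale_step

            u = _kernels.ffbs_modes(ytilde, mu, rho, sig2_w, sig2_eps, rng.standard_normal((m_modes, T)))
            w_obs = AV @ u

        # (iii) nugget variance | rest — inverse gamma
        if config.fixed_nugget_variance is None:
            resid2 = Zc - (X @ beta)[None, :] - w_obs
            scale = config.nugget_ig_scale + 0.5 * float(np.sum(resid2 * resid2))
            shape = config.nugget_ig_shape + 0.5 * N * T
            sig2_eps = scale / rng.gamma(shape, 1.0)

        if not (np.all(np.isfinite(beta)) and np.isfinite(sig2_eps) and np.isfinite(sig2_w)):
            raise DivergenceError("non-finite parameter values in Gibbs sweep", iteration=sweep)

        k = sweep - config.n_burnin
        if k >= 0:
            out_beta[k] = beta
            out_s2e[k] = sig2_eps
            out_s2w[k] = sig2_w if config.sample_process else 0.0
            out_rho[k] = rho

    return PosteriorSamples(
        beta=out_beta,
        sigma2_nugget=out_s2e,
        sigma2_process=out_s2w,
        rho=out_rho,
        region_id=region_id,
        seed=config.seed,
        config=config.echo(),
        diagnostics={
            "n_cells": N,
            "n_months": T,
            "n_missing": n_missing,
            "n_modes": m_modes,
            "mh_acceptance": n_accept / n_total if config.sample_process else None,
        },
    )
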