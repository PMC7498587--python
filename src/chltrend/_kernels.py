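"""Numba inner loops for the spatio-temporal Gibbs sampler.

The latent process is sampled jointly over time by forward filtering /
backward sampling.  Working in a basis that simultaneously diagonalizes
the innovation covariance and the observation normal-equations matrix
decouples the state into independent scalar AR(1) chains, so the filter
is O(modes x months) per sweep.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def ffbs_modes(y, mu, rho, sig2w, sig2eps, z):
    """Sample latent modes u (m x T) given mode-space observations.

    y[k, t] is the effective scalar observation of mode k at time t (the
    projected residual divided by mu[k]); its noise variance is
    sig2eps / mu[k].  State dynamics: u_t = rho u_{t-1} + N(0, sig2w),
    stationary initial distribution.  z supplies standard normals for the
    backward pass.
    """
    m, T = y.shape
    u = np.empty((m, T))
    fm = np.empty(T)
    fc = np.empty(T)
    for k in range(m):
        if mu[k] <= 0.0:
            # unobserved mode: sample from the prior AR(1)
            prev = math.sqrt(sig2w / (1.0 - rho * rho)) * z[k, 0]
            u[k, 0] = prev
            for t in range(1, T):
                prev = rho * prev + math.sqrt(sig2w) * z[k, t]
                u[k, t] = prev
            continue
        s = sig2eps / mu[k]
        mm = 0.0
        cc = sig2w / (1.0 - rho * rho)
        for t in range(T):
            if t > 0:
                mm = rho * mm
                cc = rho * rho * cc + sig2w
            g = cc / (cc + s)
            mm = mm + g * (y[k, t] - mm)
            cc = cc * (1.0 - g)
            fm[t] = mm
            fc[t] = cc
        last = fm[T - 1] + math.sqrt(max(fc[T - 1], 0.0)) * z[k, T - 1]
        u[k, T - 1] = last
        for t in range(T - 2, -1, -1):
            denom = rho * rho * fc[t] + sig2w
            if denom > 0.0:
                g = rho * fc[t] / denom
            else:
                g = 0.0
            mean = fm[t] + g * (last - rho * fm[t])
            var = fc[t] * (1.0 - g * rho)
            last = mean + math.sqrt(max(var, 0.0)) * z[k, t]
            u[k, t] = last
    return u


@njit(cache=False)
def ar1_noise_loglik(y, mu, rho, sig2w, sig2eps):
    """Log-likelihood of the mode observations with the latent AR(1) integrated out.

    Prediction-error decomposition of the scalar state-space model
    y_t = u_t + N(0, sig2eps/mu_k), u_t = rho u_{t-1} + N(0, sig2w),
    summed over observed modes; constants common to all (rho, sig2w) drop.
    """
    m, T = y.shape
    ll = 0.0
    for k in range(m):
        if mu[k] <= 0.0:
            continue
        s = sig2eps / mu[k]
        mm = 0.0
        cc = sig2w / (1.0 - rho * rho)
        for t in range(T):
            if t > 0:
                mm = rho * mm
                cc = rho * rho * cc + sig2w
            f = cc + s
            v = y[k, t] - mm
            ll += -0.5 * (math.log(f) + v * v / f)
            g = cc / f
            mm = mm + g * v
            cc = cc * (1.0 - g)
    return ll


@njit(cache=False)
def ar1_quadratics(u):
    """(q1, A, B, C) scalars for the rho and process-variance conditionals.

    q1 = ||u_1||^2; A, B, C accumulate sum ||u_t||^2, sum u_t.u_{t-1} and
    sum ||u_{t-1}||^2 over t >= 2 (modes have unit innovation scale).
    """
    m, T = u.shape
    q1 = 0.0
    A = 0.0
    B = 0.0
    C = 0.0
    for k in range(m):
        q1 += u[k, 0] * u[k, 0]
        for t in range(1, T):
            A += u[k, t] * u[k, t]
            B += u[k, t] * u[k, t - 1]
            C += u[k, t - 1] * u[k, t - 1]
    return q1, A, B, C
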