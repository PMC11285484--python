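"""Wiener diffusion first-passage-time density.

Density of the first hitting time of a drift-diffusion process (unit
diffusion coefficient, boundary separation ``alpha``, relative start
``beta``, drift ``delta``, non-decision shift ``tau``) at the lower or
upper boundary. The zero-drift unit-boundary kernel is evaluated with
the small-time and large-time series expansions, switching per time
point to whichever needs fewer terms at the requested truncation error;
drift and scale enter through an exact exponential tilt. The upper-
boundary density follows from the reflection identity
``f_upper(t; delta, beta) = f_lower(t; -delta, 1 - beta)``.
"""

from __future__ import annotations

import math

import numpy as np

from .simulate import DDMParams

__all__ = ["wiener_log_density", "wiener_density", "wiener_log_density_trials"]

_MAX_TERMS = 64


def _kernel_log(tt: np.ndarray, w: float, err: float) -> np.ndarray:
    """log f1(tt, w): first-passage density at 0 of zero-drift Brownian
    motion from w in [0, 1] with unit boundary, in normalized time tt."""
    tt = np.asarray(tt, dtype=float)
    out = np.full(tt.shape, -np.inf)
    pos = tt > 0
    t = tt[pos]

    # terms needed (Navarro & Fuss 2009 bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(0.0, -2.0 * t * np.log(
            2.0 * err * np.sqrt(2.0 * np.pi * t))))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0,
                      np.maximum(ks, np.sqrt(t) + 1.0), 2.0)
        kl = np.sqrt(np.maximum(0.0, -2.0 * np.log(np.pi * t * err)
                                / (np.pi ** 2 * t)))
        kl = np.where(np.pi * t * err < 1.0,
                      np.maximum(kl, 1.0 / (np.pi * np.sqrt(t))),
                      1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    dens = np.empty(t.shape)

    if use_small.any():
        ts = t[use_small]
        K = min(_MAX_TERMS, int(np.ceil(ks[use_small].max())))
        k = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        wk = w + 2.0 * k[:, None]
        series = np.sum(wk * np.exp(-wk ** 2 / (2.0 * ts[None, :])), axis=0)
        dens[use_small] = series / np.sqrt(2.0 * np.pi * ts ** 3)

    if (~use_small).any():
        tl = t[~use_small]
        K = min(_MAX_TERMS, int(np.ceil(kl[~use_small].max())))
        k = np.arange(1, K + 1)
        series = np.sum(k[:, None]
                        * np.exp(-(k[:, None] ** 2) * np.pi ** 2
                                 * tl[None, :] / 2.0)
                        * np.sin(k[:, None] * np.pi * w), axis=0)
        dens[~use_small] = np.pi * series

    with np.errstate(divide="ignore", invalid="ignore"):
        logd = np.log(np.maximum(dens, 0.0))
    out[pos] = logd
    return out


def wiener_log_density(rt, boundary: str, params: DDMParams,
                       err: float = 1e-7,
                       strict: bool = False) -> np.ndarray | float:
    """Log first-passage density at the named boundary.

    ``rt`` may be a scalar or array of response times (including the
    non-decision time tau). Times at or below tau get log-density -inf
    unless ``strict`` is set, in which case they raise.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    rt_arr = np.asarray(rt, dtype=float)
    t = rt_arr - params.tau
    if strict and np.any(t <= 0):
        raise ValueError("rt must exceed the non-decision time tau")
    a, w, v = params.alpha, params.beta, params.delta
    if boundary == "upper":
        w, v = 1.0 - w, -v
    tt = np.where(t > 0, t, np.nan) / a ** 2
    logf = _kernel_log(np.nan_to_num(tt, nan=-1.0), w, err)
    with np.errstate(invalid="ignore"):
        logf = logf - v * a * w - v ** 2 * np.maximum(t, 0.0) / 2.0 \
            - 2.0 * math.log(a)
    logf = np.where(t > 0, logf, -np.inf)
    return float(logf) if np.ndim(rt) == 0 else logf


def wiener_density(rt, boundary: str, params: DDMParams,
                   err: float = 1e-7) -> np.ndarray | float:
    """First-passage density (see :func:`wiener_log_density`)."""
    return np.exp(wiener_log_density(rt, boundary, params, err=err))


def wiener_log_density_trials(rt: np.ndarray, upper: np.ndarray,
                              alpha: np.ndarray, beta: np.ndarray,
                              delta: np.ndarray, tau: np.ndarray,
                              err: float = 1e-7) -> np.ndarray:
    """Vectorized log-density for trials with *per-trial* parameters.

    Workhorse of the hierarchical sampler: every argument is an array of
    one entry per trial (``upper`` boolean: which boundary was hit).
    Invalid times (rt <= tau) yield -inf.
    """
    rt = np.asarray(rt, dtype=float)
    upper = np.asarray(upper, dtype=bool)
    alpha = np.broadcast_to(np.asarray(alpha, float), rt.shape)
    w = np.where(upper, 1.0 - np.asarray(beta, float),
                 np.asarray(beta, float))
    v = np.where(upper, -np.asarray(delta, float),
                 np.asarray(delta, float))
    t = rt - np.asarray(tau, float)
    valid = t > 0
    tt = np.where(valid, t, 1.0) / alpha ** 2

    # term counts per trial, then one shared (conservative) count per branch
    with np.errstate(invalid="ignore", divide="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(0.0, -2.0 * tt * np.log(
            2.0 * err * np.sqrt(2.0 * np.pi * tt))))
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0,
                      np.maximum(ks, np.sqrt(tt) + 1.0), 2.0)
        kl = np.sqrt(np.maximum(0.0, -2.0 * np.log(np.pi * tt * err)
                                / (np.pi ** 2 * tt)))
        kl = np.where(np.pi * tt * err < 1.0,
                      np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt))),
                      1.0 / (np.pi * np.sqrt(tt)))
    use_small = ks < kl
    dens = np.empty(rt.shape)

    if use_small.any():
        ts = tt[use_small]
        ws = w[use_small]
        K = min(_MAX_TERMS, int(np.ceil(ks[use_small].max())))
        half = (K - 1) // 2 + 1
        k = np.arange(-half, half + 1)
        wk = ws[None, :] + 2.0 * k[:, None]
        series = np.sum(wk * np.exp(-wk ** 2 / (2.0 * ts[None, :])), axis=0)
        dens[use_small] = series / np.sqrt(2.0 * np.pi * ts ** 3)

    big = ~use_small
    if big.any():
        tl = tt[big]
        wl = w[big]
        K = min(_MAX_TERMS, int(np.ceil(kl[big].max())))
        k = np.arange(1, K + 1)[:, None]
        series = np.sum(k * np.exp(-(k ** 2) * np.pi ** 2 * tl[None, :] / 2.0)
                        * np.sin(k * np.pi * wl[None, :]), axis=0)
        dens[big] = np.pi * series

    with np.errstate(divide="ignore", invalid="ignore"):
        logf = (np.log(np.maximum(dens, 0.0))
                - v * alpha * w - v ** 2 * np.where(valid, t, 0.0) / 2.0
                - 2.0 * np.log(alpha))
    return np.where(valid, logf, -np.inf)
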