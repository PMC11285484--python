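"""Hyperbolic discounting fits: curve fitting and trial-level MLE.

The discounting function is v = V / (1 + k D): V is the generosity
intercept (HKD forgone for the closest person), k the discount rate per
social-distance unit. Two estimation routes are provided:

* :func:`fit_hyperbolic` — ordinary least squares of the hyperbola to a
  participant's amounts forgone (profiled: V is linear given k, so the
  search is a robust 1-D minimization over log k);
* :func:`fit_mle` — trial-level maximum likelihood under the softmax
  choice rule, optimizing (ln k, V, ln sigma) from a deterministic
  multistart grid after removing skipped trials and fast guesses
  (rt < 0.3 s by default).

k is reported with its natural log (the analysis-scale parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .modelfree import DiscountProfile
from .task import TaskDesign

__all__ = ["DiscountFit", "hyperbolic_value", "fit_hyperbolic",
           "trial_negative_loglik", "fit_mle", "fit_mle_cohort"]

K_BOUNDS = (1e-6, 10.0)
V_BOUNDS = (0.0, 1000.0)
SIGMA_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class DiscountFit:
    """Result of a discounting fit for one participant.

    ``sigma``/``loglik`` are populated only by the MLE route. ``notes``
    carries quality flags such as 'k_at_lower_bound' or
    'weakly_identified'.
    """

    participant_id: str
    k: float
    log_k: float
    V: float
    sigma: float | None
    loglik: float | None
    converged: bool
    n_trials_used: int
    notes: str = ""


def hyperbolic_value(V: float, k: float, D) -> float | np.ndarray:
    """Discounted generosity premium V / (1 + k D)."""
    D = np.asarray(D, dtype=float)
    if V < 0 or k < 0 or np.any(D < 0):
        raise ValueError("V, k and D must be non-negative")
    out = V / (1.0 + k * D)
    return float(out) if out.ndim == 0 else out


def _sse_profiled(log_k: float, D: np.ndarray,
                  y: np.ndarray) -> tuple[float, float]:
    """SSE at the OLS-optimal V for fixed k; returns (sse, V_hat)."""
    basis = 1.0 / (1.0 + math.exp(log_k) * D)
    denom = float(basis @ basis)
    V = max(0.0, float(y @ basis) / denom)
    resid = y - V * basis
    return float(resid @ resid), V


def fit_hyperbolic(profile: DiscountProfile,
                   participant_id: str | None = None) -> DiscountFit:
    """Least-squares hyperbola through a participant's amounts forgone.

    Needs at least three distances. V is profiled out analytically, and
    k is found by a log-spaced grid scan refined with bounded scalar
    minimization. A flat profile leaves k unidentified: it is pinned to
    the lower bound and flagged.
    """
    D = np.asarray(profile.distances, dtype=float)
    y = np.asarray(profile.amounts_forgone, dtype=float)
    mask = np.isfinite(y)
    D, y = D[mask], y[mask]
    if D.size < 3:
        raise ValueError("need >= 3 distances with finite forgone amounts")
    pid = participant_id or profile.participant_id

    lo, hi = math.log(K_BOUNDS[0]), math.log(K_BOUNDS[1])
    grid = np.linspace(lo, hi, 60)
    sses = np.array([_sse_profiled(g, D, y)[0] for g in grid])
    i = int(np.argmin(sses))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda g: _sse_profiled(g, D, y)[0],
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    log_k = float(res.x)
    sse, V = _sse_profiled(log_k, D, y)
    # unidentified curvature: no improvement over the no-discounting fit
    flat = np.allclose(y, y[0]) or sses[0] <= sse * (1 + 1e-9)
    notes = ""
    if flat:
        log_k, (sse, V) = lo, _sse_profiled(lo, D, y)
        notes = "k_at_lower_bound"
    k = math.exp(log_k)
    return DiscountFit(pid, k=k, log_k=log_k, V=V, sigma=None, loglik=None,
                       converged=bool(res.success) and not flat,
                       n_trials_used=int(D.size), notes=notes)


def trial_negative_loglik(k: float, V: float, sigma: float,
                          distances, selfish_amounts, choices,
                          generous_amount: float = 130.0) -> float:
    """Negative log-likelihood of scored trials under the softmax rule.

    ``choices`` is 0/1 with 1 = selfish. Uses log1p/exp formulations so
    extreme value differences do not overflow.
    """
    D = np.asarray(distances, dtype=float)
    A = np.asarray(selfish_amounts, dtype=float)
    y = np.asarray(choices).astype(bool)
    if D.size == 0:
        raise ValueError("empty trial set")
    z = sigma * (A - (generous_amount + V / (1.0 + k * D)))
    # log p(selfish) = -log1p(e^{-z}); log p(generous) = -log1p(e^{z})
    signed = np.where(y, -z, z)
    return float(np.sum(np.logaddexp(0.0, signed)))


_START_K = (0.01, 0.1, 1.0)
_START_V = (50.0, 170.0, 400.0)
_START_SIGMA = (0.01, 0.05, 0.5)


def fit_mle(trials: pd.DataFrame,
            design: TaskDesign | None = None,
            rt_floor: float | None = None,
            min_trials: int = 20,
            participant_id: str | None = None) -> DiscountFit:
    """Trial-level MLE of (k, V, sigma) for one participant.

    Skipped trials and trials faster than ``rt_floor`` seconds (design
    default 0.3 s) are removed first; at least ``min_trials`` must
    remain. The optimizer runs L-BFGS-B over (ln k, V, ln sigma) from a
    deterministic 3 x 3 x 3 start grid, so the fit is reproducible and
    invariant to trial order.
    """
    design = design or TaskDesign()
    if rt_floor is None:
        rt_floor = design.rt_floor
    scored = trials[trials["choice"] != "skipped"]
    scored = scored[scored["rt"] >= rt_floor]
    n = len(scored)
    if n < min_trials:
        raise ValueError(
            f"only {n} scored trials after the {rt_floor} s filter "
            f"(need >= {min_trials})")
    pid = participant_id or str(trials["participant_id"].iloc[0])
    D = scored["distance"].to_numpy(dtype=float)
    A = scored["selfish_amount"].to_numpy(dtype=float)
    y = (scored["choice"] == "selfish").to_numpy()

    def nll(x: np.ndarray) -> float:
        return trial_negative_loglik(math.exp(x[0]), x[1], math.exp(x[2]),
                                     D, A, y, design.generous_amount)

    bounds = [(math.log(K_BOUNDS[0]), math.log(K_BOUNDS[1])),
              V_BOUNDS,
              (math.log(SIGMA_BOUNDS[0]), math.log(SIGMA_BOUNDS[1]))]
    best = None
    for k0 in _START_K:
        for V0 in _START_V:
            for s0 in _START_SIGMA:
                x0 = np.array([math.log(k0), V0, math.log(s0)])
                res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                        bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
    assert best is not None
    log_k, V, log_sigma = best.x
    sigma = math.exp(log_sigma)
    notes = ""
    if sigma < 5e-3:
        # near-coin-flip regime: value differences of ~100 HKD move the
        # choice probability by only a few points, so (k, V) are barely
        # constrained by the likelihood
        notes = "weakly_identified"
    return DiscountFit(pid, k=math.exp(log_k), log_k=float(log_k),
                       V=float(V), sigma=float(sigma),
                       loglik=float(-best.fun), converged=bool(best.success),
                       n_trials_used=n, notes=notes)


def fit_mle_cohort(dataset, rt_floor: float | None = None,
                   min_trials: int = 20) -> pd.DataFrame:
    """MLE fits for every participant of a cohort; participants with too
    few scored trials are recorded with NaN estimates and a note."""
    rows = []
    cells = dataset.participant_cells().set_index("participant_id")
    for pid, trials in dataset.trials.groupby("participant_id", sort=False):
        base = {"participant_id": pid, "sex": cells.loc[pid, "sex"],
                "condition": cells.loc[pid, "condition"]}
        try:
            fit = fit_mle(trials, dataset.design, rt_floor=rt_floor,
                          min_trials=min_trials, participant_id=str(pid))
            base.update(k=fit.k, log_k=fit.log_k, V=fit.V, sigma=fit.sigma,
                        loglik=fit.loglik, converged=fit.converged,
                        n_trials_used=fit.n_trials_used, notes=fit.notes)
        except ValueError as exc:
            base.update(k=np.nan, log_k=np.nan, V=np.nan, sigma=np.nan,
                        loglik=np.nan, converged=False, n_trials_used=0,
                        notes=str(exc))
        rows.append(base)
    return pd.DataFrame(rows)
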