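"""Model-free prosociality: indifference points and discounting AUC.

For each participant and social distance, a logistic regression of choice
(selfish = 1) on the selfish amount yields the indifference point — the
amount at which the selfish option is chosen with probability 0.5. One-
sided response patterns are imputed half an increment outside the amount
range (120 and 300 HKD under the default design); perfectly separated
mixed patterns resolve to the midpoint of the separating gap. Amounts
forgone (indifference minus the 130 HKD generous amount) are then
normalized and integrated over normalized social distance by the
trapezoid rule, giving an AUC in [0, 1]: 0 is maximal discounting, 1 no
discounting at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ChoiceDataset
from .task import TaskDesign

__all__ = ["DiscountProfile", "AUCResult", "fit_indifference_point",
           "amount_forgone", "compute_auc", "profile_participant",
           "profile_cohort"]


@dataclass
class DiscountProfile:
    """Per-participant indifference points by social distance."""

    participant_id: str
    distances: np.ndarray
    indifference_points: np.ndarray
    methods: list[str] = field(default_factory=list)
    generous_amount: float = 130.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.indifference_points = np.asarray(self.indifference_points,
                                              dtype=float)
        if self.distances.shape != self.indifference_points.shape:
            raise ValueError("distances and indifference_points must align")

    @property
    def amounts_forgone(self) -> np.ndarray:
        """Raw amounts forgone (may be negative for the low imputation)."""
        return self.indifference_points - self.generous_amount


@dataclass(frozen=True)
class AUCResult:
    participant_id: str
    auc: float
    n_distances_used: int


def fit_indifference_point(
    selfish_amounts: np.ndarray,
    choices: np.ndarray,
    design: TaskDesign | None = None,
) -> tuple[float, str]:
    """Indifference point from one participant's trials at one distance.

    ``choices`` is boolean/0-1 with 1 = selfish. Returns the point and the
    estimation method: 'imputed_low' (all selfish: half an increment below
    the smallest amount), 'imputed_high' (all generous), a deterministic
    'separation_midpoint' when the responses are perfectly separated in
    amount, else 'logistic' — the MLE crossing -intercept/slope clipped to
    the imputation bounds.

    Raises ``ValueError`` on an empty (all-skipped) trial set.
    """
    design = design or TaskDesign()
    amounts = np.asarray(selfish_amounts, dtype=float)
    y = np.asarray(choices).astype(int)
    if amounts.size == 0:
        raise ValueError("no scored trials at this distance")
    lo, hi = design.imputed_low, design.imputed_high
    if y.all():
        return lo, "imputed_low"
    if not y.any():
        return hi, "imputed_high"
    a_selfish = amounts[y == 1]
    a_generous = amounts[y == 0]
    if a_generous.max() < a_selfish.min():
        return float((a_generous.max() + a_selfish.min()) / 2.0), "separation_midpoint"
    if a_selfish.max() < a_generous.min():  # reversed preference, still separated
        return float((a_selfish.max() + a_generous.min()) / 2.0), "separation_midpoint"
    X = sm.add_constant(amounts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            b0, b1 = res.params
            point = -b0 / b1 if b1 != 0 else np.nan
        except Exception:
            point = np.nan
    if not np.isfinite(point):
        # degenerate likelihood: interpolate from the overall selfish rate
        point = hi - y.mean() * (hi - lo)
    return float(np.clip(point, lo, hi)), "logistic"


def amount_forgone(indifference_point: float,
                   design: TaskDesign | None = None) -> float:
    """Cost of being generous: indifference point minus the generous amount."""
    design = design or TaskDesign()
    if not design.imputed_low <= indifference_point <= design.imputed_high:
        raise ValueError(
            f"indifference point {indifference_point} outside "
            f"[{design.imputed_low}, {design.imputed_high}]")
    return float(indifference_point - design.generous_amount)


def compute_auc(profile: DiscountProfile,
                design: TaskDesign | None = None) -> AUCResult:
    """Normalized trapezoidal area under the discounting curve.

    y is the amount forgone clipped below at 0 and divided by the
    theoretical maximum forgone (170 HKD under the default design); x is
    distance divided by the largest design distance. An anchor at x = 0
    carries the smallest-distance y so that a flat maximal profile
    integrates to exactly 1.
    """
    design = design or TaskDesign()
    order = np.argsort(profile.distances)
    d = profile.distances[order]
    v = profile.amounts_forgone[order]
    mask = np.isfinite(v)
    d, v = d[mask], v[mask]
    if d.size < 2:
        raise ValueError("need at least two distances with finite forgone")
    y = np.clip(v, 0.0, None) / design.max_forgone
    x = d / max(design.distances)
    x = np.concatenate([[0.0], x])
    y = np.concatenate([[y[0]], y])
    auc = float(np.trapezoid(y, x))
    return AUCResult(profile.participant_id, auc, int(d.size))


def profile_participant(trials: pd.DataFrame,
                        design: TaskDesign | None = None) -> DiscountProfile:
    """Indifference-point profile from one participant's scored trials."""
    design = design or TaskDesign()
    scored = trials[trials["choice"] != "skipped"]
    pid = str(trials["participant_id"].iloc[0])
    dists, points, methods = [], [], []
    for dist, grp in scored.groupby("distance", sort=True):
        point, method = fit_indifference_point(
            grp["selfish_amount"].to_numpy(),
            (grp["choice"] == "selfish").to_numpy(), design)
        dists.append(dist)
        points.append(point)
        methods.append(method)
    return DiscountProfile(pid, np.asarray(dists, float),
                           np.asarray(points, float), methods,
                           generous_amount=design.generous_amount)


def profile_cohort(dataset: ChoiceDataset) -> tuple[list[DiscountProfile],
                                                    pd.DataFrame]:
    """Profiles and AUC table (participant_id, sex, condition, auc) for a
    whole cohort."""
    design = dataset.design
    cells = dataset.participant_cells().set_index("participant_id")
    profiles, rows = [], []
    for pid, trials in dataset.trials.groupby("participant_id", sort=False):
        prof = profile_participant(trials, design)
        profiles.append(prof)
        res = compute_auc(prof, design)
        rows.append({"participant_id": pid,
                     "sex": cells.loc[pid, "sex"],
                     "condition": cells.loc[pid, "condition"],
                     "auc": res.auc,
                     "n_distances_used": res.n_distances_used})
    return profiles, pd.DataFrame(rows)
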