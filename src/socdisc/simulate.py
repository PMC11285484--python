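"""Synthetic choice/response-time cohorts with known ground truth.

Two generative modes mirror the two model families fitted downstream:

* *softmax mode* — choices are Bernoulli draws from the hyperbolic-
  discounting + softmax choice rule (placeholder lognormal RTs, since the
  softmax model is silent about time);
* *diffusion mode* — choices and RTs are drawn jointly from a drift-
  diffusion process (Euler-Maruyama with a Brownian-bridge crossing
  correction), the upper boundary mapping to the selfish option by
  default.

Cohorts are laid out as 2 sex x 2 condition cells with per-participant
parameter dispersion (log-normal for positive parameters, logit-normal
for the start bias, normal for drift) and optional contamination:
fast guesses below the RT floor and skipped (twice-unanswered) trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChoiceDataset, TrialRecord, COLUMNS
from .task import TaskDesign, build_trial_grid, UPPER_BOUNDARY_CHOICE

__all__ = [
    "AgentParams", "DDMParams", "CohortTruth", "choice_probability",
    "simulate_ddm_trial", "simulate_ddm_trials", "analytic_upper_probability",
    "simulate_participant", "simulate_cohort", "default_truth",
]

CELLS = [("female", "androstadienone"), ("female", "control"),
         ("male", "androstadienone"), ("male", "control")]


@dataclass(frozen=True)
class AgentParams:
    """Hyperbolic-discounting softmax agent.

    k
        Discount rate per social-distance unit; larger k, steeper decline
        of generosity with distance.
    V
        Generosity intercept (HKD): amount forgone at distance zero.
    sigma
        Softmax inverse temperature (per HKD): sensitivity of choice to
        the subjective value difference. sigma = 0 is pure coin-flipping.
    """

    k: float
    V: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("k", "V", "sigma"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters (unit diffusion coefficient).

    alpha: boundary separation (evidence units); beta: relative starting
    point in (0, 1); delta: drift rate (evidence/s), positive drifting
    toward the upper boundary; tau: non-decision time (s), at least 0.1 s.
    """

    alpha: float
    beta: float
    delta: float
    tau: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if not self.tau >= 0.1:
            raise ValueError("tau must be >= 0.1 s")


# Between-participant dispersions: SD on the log scale for positive
# parameters, on the logit scale for beta, raw SD for delta.
DEFAULT_DISPERSION = {
    "k": 0.5, "V": 0.35, "sigma": 0.4,
    "alpha": 0.2, "beta": 0.3, "delta": 0.3, "tau": 0.15,
}


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth for a simulated 2 x 2 cohort.

    ``cell_agent``/``cell_ddm`` give per-cell central parameters (the
    median of the between-participant distribution); ``dispersion`` the
    between-participant SDs on each parameter's sampling scale.
    """

    n_per_cell: int
    cell_agent: dict
    cell_ddm: dict | None
    dispersion: dict = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    fast_guess_rate: float = 0.0
    skip_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        for r in (self.fast_guess_rate, self.skip_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("contamination rates must lie in [0, 1)")
        if any(v < 0 for v in self.dispersion.values()):
            raise ValueError("dispersions must be non-negative")
        for cell in CELLS:
            if cell not in self.cell_agent:
                raise ValueError(f"cell_agent missing cell {cell}")
            if self.cell_ddm is not None and cell not in self.cell_ddm:
                raise ValueError(f"cell_ddm missing cell {cell}")


def default_truth(
    n_per_cell: int = 10,
    seed: int | None = None,
    fast_guess_rate: float = 0.03,
    skip_rate: float = 0.02,
    dispersion: dict | None = None,
    with_ddm: bool = True,
) -> CohortTruth:
    """Null-effect cohort truth at realistic central values.

    Central values echo typical social-discounting samples: k = 0.15 (the
    amount forgone halves by distance ~7), V = 170 HKD, softmax sigma =
    0.05/HKD; diffusion alpha = 1.5, beta = 0.5, delta = 0.3, tau = 0.35 s.
    All four cells share the same parameters (no sex/condition effects).
    """
    agent = AgentParams(k=0.15, V=170.0, sigma=0.05)
    ddm = DDMParams(alpha=1.5, beta=0.5, delta=0.3, tau=0.35)
    return CohortTruth(
        n_per_cell=n_per_cell,
        cell_agent={c: agent for c in CELLS},
        cell_ddm={c: ddm for c in CELLS} if with_ddm else None,
        dispersion=dict(dispersion or DEFAULT_DISPERSION),
        fast_guess_rate=fast_guess_rate,
        skip_rate=skip_rate,
        seed=seed,
    )


def choice_probability(
    agent: AgentParams,
    distance: float,
    selfish_amount: float,
    generous_amount: float = 130.0,
) -> float:
    """Probability of the selfish choice under the softmax rule.

    The generous option's subjective value is the generous amount plus the
    hyperbolically discounted generosity premium V/(1+kD); the selfish
    option's value is its monetary amount A. Then
    ``p = 1 / (1 + exp(-sigma * (A - (G + V/(1+kD)))))``.
    """
    value_generous = generous_amount + agent.V / (1.0 + agent.k * distance)
    z = agent.sigma * (selfish_amount - value_generous)
    # logistic via tanh for symmetry-exact p=0.5 at z=0
    return float(0.5 * (1.0 + math.tanh(z / 2.0)))


def analytic_upper_probability(ddm: DDMParams) -> float:
    """Exact probability that drifted Brownian motion from beta*alpha hits
    alpha before 0: (1 - e^{-2 d b a}) / (1 - e^{-2 d a}); beta at zero
    drift."""
    d, a, b = ddm.delta, ddm.alpha, ddm.beta
    if abs(d) < 1e-12:
        return b
    return float(-math.expm1(-2.0 * d * b * a) / -math.expm1(-2.0 * d * a))


def simulate_ddm_trials(
    ddm: DDMParams,
    n: int,
    rng: np.random.Generator,
    dt: float = 0.001,
    t_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized first-passage simulation of ``n`` diffusion trials.

    Euler-Maruyama with step ``dt`` from ``beta*alpha``, unit diffusion,
    absorbing boundaries at 0 and alpha. Between steps, absorption is
    resolved with the exact Brownian-bridge crossing probability
    ``exp(-2 (a - x0)(a - x1) / dt)``, making the first-passage bias
    O(dt) instead of O(sqrt(dt)).

    Returns ``(upper, rt)``: a boolean array (True = upper boundary) and
    decision times plus the non-decision time tau.
    """
    if dt <= 0:
        raise ValueError("step size dt must be positive")
    a, b, d = ddm.alpha, ddm.beta, ddm.delta
    x = np.full(n, b * a)
    idx = np.arange(n)
    upper = np.zeros(n, dtype=bool)
    t_hit = np.full(n, np.nan)
    sqdt = math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for step in range(n_steps):
        if idx.size == 0:
            break
        x_new = x + d * dt + sqdt * rng.standard_normal(idx.size)
        hit_up = x_new >= a
        hit_low = x_new <= 0.0
        open_ = ~(hit_up | hit_low)
        if open_.any():
            xo, xn = x[open_], x_new[open_]
            p_up = np.exp(-2.0 * (a - xo) * (a - xn) / dt)
            p_low = np.exp(-2.0 * xo * xn / dt)
            u = rng.random(xo.size)
            bridge_up = u < p_up
            bridge_low = (~bridge_up) & (u < p_up + p_low)
            tmp_up = hit_up.copy()
            tmp_low = hit_low.copy()
            tmp_up[open_] = bridge_up
            tmp_low[open_] = bridge_low
            hit_up, hit_low = tmp_up, tmp_low
        absorbed = hit_up | hit_low
        if absorbed.any():
            hit_ids = idx[absorbed]
            upper[hit_ids] = hit_up[absorbed]
            t_hit[hit_ids] = (step + 1) * dt
            keep = ~absorbed
            idx, x = idx[keep], x_new[keep]
        else:
            x = x_new
    if idx.size:  # censored walks: resolve by the analytic hitting law
        if abs(d) < 1e-12:
            p = x / a
        else:
            p = -np.expm1(-2.0 * d * x) / -math.expm1(-2.0 * d * a)
        upper[idx] = rng.random(idx.size) < p
        t_hit[idx] = t_max
    return upper, t_hit + ddm.tau


def simulate_ddm_trial(
    ddm: DDMParams,
    seed: int | np.random.Generator,
    dt: float = 0.001,
) -> tuple[str, float]:
    """One diffusion trial; returns ('upper'|'lower', rt)."""
    if seed is None:
        raise ValueError("a seed (or Generator) is required")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    up, rt = simulate_ddm_trials(ddm, 1, rng, dt=dt)
    return ("upper" if up[0] else "lower", float(rt[0]))


def _placeholder_rt(rng: np.random.Generator, window: float) -> float:
    # softmax mode carries no RT model; lognormal with median ~0.85 s
    rt = 0.25 + rng.lognormal(mean=math.log(0.6), sigma=0.4)
    return float(min(rt, window))


def simulate_participant(
    agent: AgentParams,
    ddm: DDMParams | None,
    design: TaskDesign,
    seed: int | np.random.Generator,
    participant_id: str = "p000",
    sex: str = "female",
    condition: str = "control",
    fast_guess_rate: float = 0.0,
    skip_rate: float = 0.0,
    upper_boundary_choice: str = UPPER_BOUNDARY_CHOICE,
    dt: float = 0.001,
) -> list[TrialRecord]:
    """Simulate one participant's full session: one record per grid pair.

    With ``ddm`` supplied, choices and RTs come jointly from the diffusion
    process (upper boundary mapped to ``upper_boundary_choice``); without
    it, choices are softmax Bernoulli draws with placeholder RTs. A trial
    is emitted as ``skipped`` if it went unanswered both at first
    presentation and at its one end-of-block re-presentation (probability
    ``skip_rate``), or if the diffusion RT exceeded the response window.
    Fast guesses (random choice, rt below the RT floor) are injected at
    ``fast_guess_rate``.
    """
    if seed is None:
        raise ValueError("a seed (or Generator) is required for simulation")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    grid = build_trial_grid(design, rng)
    records: list[TrialRecord] = []
    if ddm is not None:
        uppers, rts = simulate_ddm_trials(ddm, len(grid), rng, dt=dt)
    for i, (dist, amount) in enumerate(grid):
        u = rng.random()
        if u < skip_rate:
            records.append(TrialRecord(participant_id, sex, condition,
                                       dist, amount, "skipped", None))
            continue
        if u < skip_rate + fast_guess_rate:
            # strictly below the floor even after 3-decimal rounding
            rt = round(float(rng.uniform(0.05, design.rt_floor - 0.002)), 3)
            choice = "selfish" if rng.random() < 0.5 else "generous"
            records.append(TrialRecord(participant_id, sex, condition,
                                       dist, amount, choice, rt))
            continue
        if ddm is not None:
            rt = float(rts[i])
            if rt > design.response_window:
                records.append(TrialRecord(participant_id, sex, condition,
                                           dist, amount, "skipped", None))
                continue
            if uppers[i]:
                choice = upper_boundary_choice
            else:
                choice = ("generous" if upper_boundary_choice == "selfish"
                          else "selfish")
        else:
            p = choice_probability(agent, dist, amount,
                                   design.generous_amount)
            choice = "selfish" if rng.random() < p else "generous"
            rt = _placeholder_rt(rng, design.response_window)
        records.append(TrialRecord(participant_id, sex, condition,
                                   dist, amount, choice, round(rt, 3)))
    return records


def _draw_agent(mean: AgentParams, disp: dict,
                rng: np.random.Generator) -> AgentParams:
    def ln(m, s):
        return float(m * math.exp(rng.standard_normal() * s)) if m > 0 else m
    return AgentParams(k=ln(mean.k, disp.get("k", 0.0)),
                       V=ln(mean.V, disp.get("V", 0.0)),
                       sigma=ln(mean.sigma, disp.get("sigma", 0.0)))


def _draw_ddm(mean: DDMParams, disp: dict,
              rng: np.random.Generator) -> DDMParams:
    logit = lambda p: math.log(p / (1 - p))
    inv = lambda z: 1.0 / (1.0 + math.exp(-z))
    alpha = mean.alpha * math.exp(rng.standard_normal() * disp.get("alpha", 0.0))
    beta = inv(logit(mean.beta) + rng.standard_normal() * disp.get("beta", 0.0))
    delta = mean.delta + rng.standard_normal() * disp.get("delta", 0.0)
    # keep tau >= 0.1 by dispersing the excess over the floor log-normally
    tau = 0.1 + (mean.tau - 0.1) * math.exp(
        rng.standard_normal() * disp.get("tau", 0.0))
    return DDMParams(alpha=alpha, beta=beta, delta=delta, tau=tau)


def simulate_cohort(
    truth: CohortTruth,
    design: TaskDesign | None = None,
    mode: str = "auto",
    dt: float = 0.001,
) -> ChoiceDataset:
    """Simulate a full 2 sex x 2 condition cohort.

    ``mode``: 'softmax' forces choice-only simulation, 'ddm' requires
    diffusion truth, 'auto' uses the diffusion whenever ``cell_ddm`` is
    present. Participant parameters are drawn around their cell's central
    values with the truth's dispersions. Returns a :class:`ChoiceDataset`;
    the per-participant true parameters are attached as ``.truth_params``.
    """
    design = design or TaskDesign()
    if truth.seed is None:
        raise ValueError("CohortTruth.seed is required for simulation")
    if mode not in ("auto", "softmax", "ddm"):
        raise ValueError(f"unknown mode {mode!r}")
    use_ddm = (truth.cell_ddm is not None) if mode == "auto" else (mode == "ddm")
    if use_ddm and truth.cell_ddm is None:
        raise ValueError("mode='ddm' requires cell_ddm truth")
    rng = np.random.default_rng(truth.seed)
    rows: list[TrialRecord] = []
    param_rows = []
    pid = 0
    for sex, condition in CELLS:
        for _ in range(truth.n_per_cell):
            pid += 1
            participant = f"p{pid:03d}"
            agent = _draw_agent(truth.cell_agent[(sex, condition)],
                                truth.dispersion, rng)
            ddm = (_draw_ddm(truth.cell_ddm[(sex, condition)],
                             truth.dispersion, rng) if use_ddm else None)
            rows.extend(simulate_participant(
                agent, ddm, design, rng, participant_id=participant,
                sex=sex, condition=condition,
                fast_guess_rate=truth.fast_guess_rate,
                skip_rate=truth.skip_rate, dt=dt))
            rec = {"participant_id": participant, "sex": sex,
                   "condition": condition, "k": agent.k, "V": agent.V,
                   "sigma": agent.sigma}
            if ddm is not None:
                rec.update(alpha=ddm.alpha, beta=ddm.beta,
                           delta=ddm.delta, tau=ddm.tau)
            param_rows.append(rec)
    df = pd.DataFrame([{
        "participant_id": r.participant_id, "sex": r.sex,
        "condition": r.condition, "distance": r.distance,
        "selfish_amount": r.selfish_amount, "choice": r.choice,
        "rt": np.nan if r.rt is None else r.rt} for r in rows],
        columns=COLUMNS)
    dataset = ChoiceDataset(df, design)
    dataset.truth_params = pd.DataFrame(param_rows)
    return dataset
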