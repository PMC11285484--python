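"""Hierarchical Bayesian drift-diffusion inference.

Each participant has four diffusion parameters (boundary separation
alpha, start bias beta, drift delta, non-decision time tau), sampled on
transformed scales (ln alpha, logit beta, identity delta, scaled-logit
tau constrained to (0.1 s, 0.95 x the participant's fastest RT)). On
each transformed scale, participant-level values are normally
distributed around a cell mean given by a 2 x 2 linear model

    mu + b_sex * sex + b_condition * condition + b_interaction * sex*condition

with dummy coding female = 0 / male = 1, control = 0 / androstadienone
= 1. The group coefficients carry standard-normal priors and the
between-participant SDs half-normal(1) priors.

Posterior sampling is an adaptive Metropolis-within-Gibbs scheme:
participant-level parameters move by adaptively scaled random-walk
proposals against the Wiener first-passage likelihood; the group
coefficients are updated by their exact conjugate normal conditionals;
the subject SDs by a univariate slice sampler. Convergence is assessed
with the rank-normalized split R-hat (threshold 1.01), and group
differences are declared credible when the 95% highest density interval
of the corresponding coefficient excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChoiceDataset
from .task import UPPER_BOUNDARY_CHOICE
from .wiener import wiener_log_density_trials

__all__ = ["MCMCConfig", "GroupModel", "DDMPosterior", "hdi", "rhat",
           "fit_hierarchical_ddm", "credible_group_difference"]

PARAMS = ("alpha", "beta", "delta", "tau")
EFFECTS = ("mu", "sex", "condition", "interaction")
TAU_FLOOR = 0.1  # lower bound for non-decision time, seconds


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    n_in = int(math.ceil(mass * n))
    widths = x[n_in - 1:] - x[:n - n_in + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_in - 1])


def _split_rhat(z: np.ndarray) -> float:
    """Classic potential-scale-reduction on already split chains (m, n)."""
    m, n = z.shape
    means = z.mean(axis=1)
    W = z.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    if W <= 0:
        return 1.0
    return float(math.sqrt(var_hat / W))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, axis=None).reshape(x.shape)
    return stats.norm.ppf((r - 3.0 / 8.0) / (x.size + 0.25))


def rhat(chains) -> float:
    """Rank-normalized split R-hat (maximum of bulk and folded variants).

    ``chains`` is (n_chains, n_draws) with at least 2 chains of at least
    4 draws. Values near 1 (below 1.01) indicate the chains have mixed.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    m, n = x.shape
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    half = n // 2
    split = np.concatenate([x[:, :half], x[:, n - half:]], axis=0)
    if np.allclose(split, split.ravel()[0]):
        return 1.0
    bulk = _split_rhat(_rank_normalize(split))
    folded = _split_rhat(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings. ``iterations`` counts total draws per chain;
    the first ``warmup`` (default: half) adapt proposals and are
    discarded. The study-scale configuration is 4 chains x 4000."""

    chains: int = 4
    iterations: int = 1000
    warmup: int | None = None
    seed: int | None = None
    rt_floor: float = 0.3
    upper_boundary_choice: str = UPPER_BOUNDARY_CHOICE
    err: float = 1e-7

    @property
    def n_warmup(self) -> int:
        return self.iterations // 2 if self.warmup is None else self.warmup

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.n_warmup >= self.iterations:
            raise ValueError("warmup must leave post-warmup draws")


@dataclass(frozen=True)
class GroupModel:
    """Posterior-mean group-level model: per diffusion parameter, the
    grand mean, the three effect coefficients (transformed scale) and the
    between-participant SD."""

    mu: dict
    beta_sex: dict
    beta_condition: dict
    beta_interaction: dict
    subject_sd: dict


@dataclass
class DDMPosterior:
    """Posterior draws and summaries of the hierarchical DDM fit."""

    draws: dict                      # name -> (chains, post-warmup draws)
    rhat: dict                       # name -> rank-normalized split R-hat
    hdi_95: dict                     # name -> (low, high)
    subject_summary: pd.DataFrame    # posterior-mean natural-scale params
    converged: bool
    config: MCMCConfig

    @property
    def effect_names(self) -> list[str]:
        return [f"{p}_{e}" for p in PARAMS for e in EFFECTS if e != "mu"]

    def group_model(self) -> GroupModel:
        mean = {k: float(v.mean()) for k, v in self.draws.items()}
        return GroupModel(
            mu={p: mean[f"{p}_mu"] for p in PARAMS},
            beta_sex={p: mean[f"{p}_sex"] for p in PARAMS},
            beta_condition={p: mean[f"{p}_condition"] for p in PARAMS},
            beta_interaction={p: mean[f"{p}_interaction"] for p in PARAMS},
            subject_sd={p: mean[f"{p}_subject_sd"] for p in PARAMS},
        )


def credible_group_difference(posterior: DDMPosterior,
                              coefficient: str) -> str:
    """'credible' iff the coefficient's 95% HDI excludes zero."""
    if coefficient not in posterior.hdi_95:
        raise KeyError(f"unknown coefficient {coefficient!r}")
    lo, hi = posterior.hdi_95[coefficient]
    return "credible" if (lo > 0.0 or hi < 0.0) else "not_credible"


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(z / 2.0))


class _Problem:
    """Data bundle and likelihood for the sampler."""

    def __init__(self, dataset: ChoiceDataset, config: MCMCConfig):
        scored = dataset.scored(rt_floor=config.rt_floor)
        cells = (scored.groupby("participant_id", sort=False)
                 [["sex", "condition"]].first())
        counts = cells.groupby(["sex", "condition"]).size()
        if len(counts) < 4 or counts.min() < 2:
            raise ValueError("need >= 2 participants in every sex x "
                             "condition cell")
        self.pids = list(cells.index)
        self.n_sub = len(self.pids)
        pid_to_i = {p: i for i, p in enumerate(self.pids)}
        self.subj = scored["participant_id"].map(pid_to_i).to_numpy()
        self.rt = scored["rt"].to_numpy(dtype=float)
        self.upper = (scored["choice"]
                      == config.upper_boundary_choice).to_numpy()
        sex = (cells["sex"] == "male").astype(float).to_numpy()
        cond = (cells["condition"] == "androstadienone").astype(float).to_numpy()
        self.X = np.column_stack([np.ones(self.n_sub), sex, cond, sex * cond])
        min_rt = scored.groupby("participant_id", sort=False)["rt"].min()
        self.tau_span = 0.95 * min_rt.loc[self.pids].to_numpy() - TAU_FLOOR
        if np.any(self.tau_span <= 0):
            raise ValueError("a participant's fastest RT is too close to "
                             "the 0.1 s non-decision floor")
        self.err = config.err

    def natural(self, Z: np.ndarray) -> tuple[np.ndarray, ...]:
        alpha = np.exp(Z[:, 0])
        beta = _sigmoid(Z[:, 1])
        delta = Z[:, 2]
        tau = TAU_FLOOR + _sigmoid(Z[:, 3]) * self.tau_span
        return alpha, beta, delta, tau

    def loglik(self, Z: np.ndarray) -> np.ndarray:
        """Per-subject log-likelihood vector for transformed params Z."""
        alpha, beta, delta, tau = self.natural(Z)
        ld = wiener_log_density_trials(
            self.rt, self.upper, alpha[self.subj], beta[self.subj],
            delta[self.subj], tau[self.subj], err=self.err)
        out = np.zeros(self.n_sub)
        np.add.at(out, self.subj, ld)
        return out


def _slice_sample_log_sd(logs0: float, ssr: float, n: int,
                         rng: np.random.Generator,
                         w: float = 0.5, max_steps: int = 30) -> float:
    """Slice sampler for the log subject-SD given residual sum of squares.

    Target: Normal likelihood of n residuals with scale e^ls, half-normal(1)
    prior on the SD, plus the log-scale Jacobian.
    """

    def logp(ls: float) -> float:
        s2 = math.exp(2.0 * ls)
        return (1.0 - n) * ls - ssr / (2.0 * s2) - s2 / 2.0

    y = logp(logs0) + math.log(rng.random())
    lo = logs0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) < y:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < y:
            break
        hi += w
    for _ in range(100):
        x = rng.uniform(lo, hi)
        if logp(x) >= y:
            return x
        if x < logs0:
            lo = x
        else:
            hi = x
    return logs0


def _run_chain(problem: _Problem, config: MCMCConfig,
               rng: np.random.Generator):
    S = problem.n_sub
    X = problem.X
    XtX = X.T @ X
    n_keep = config.iterations - config.n_warmup

    Z = rng.normal(scale=0.1, size=(S, 4))
    B = np.zeros((4, 4))          # rows: effects, cols: diffusion params
    B[0] = rng.normal(scale=0.1, size=4)
    log_s = np.full(4, math.log(0.5))
    scales = np.full((S, 4), 0.25)
    move_scales = np.full((5, 4), 0.1)   # translation / rescale group moves

    # per-subject joint proposal machinery (adaptive Metropolis): running
    # moments feed a covariance-shaped 4-D proposal once warmed up
    warm_count = 0
    run_mean = np.zeros((S, 4))
    run_m2 = np.zeros((S, 4, 4))
    lam = np.full(S, 0.6)                # global per-subject step factor
    prop_chol = np.tile(np.eye(4) * 0.25, (S, 1, 1))
    phase_a_end = max(50, config.n_warmup // 3)

    ll = problem.loglik(Z)
    kept_group = np.empty((n_keep, 20))
    subj_sum = np.zeros((S, 4))

    for it in range(config.iterations):
        adapting = it < config.n_warmup
        rate = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0
        cell_mean = X @ B                      # (S, 4)
        sd = np.exp(log_s)
        if it < phase_a_end:
            # phase A: componentwise random walk while covariance accrues
            for _sweep in range(2):
                for j in range(4):
                    Zp = Z.copy()
                    Zp[:, j] = Z[:, j] + scales[:, j] * rng.standard_normal(S)
                    llp = problem.loglik(Zp)
                    dprior = (-(Zp[:, j] - cell_mean[:, j]) ** 2
                              + (Z[:, j] - cell_mean[:, j]) ** 2
                              ) / (2.0 * sd[j] ** 2)
                    accept = np.log(rng.random(S)) < (llp - ll) + dprior
                    Z[accept, j] = Zp[accept, j]
                    ll = np.where(accept, llp, ll)
                    if adapting:
                        scales[:, j] *= np.exp(
                            rate * (accept.astype(float) - 0.44))
                        np.clip(scales[:, j], 1e-3, 2.0, out=scales[:, j])
        else:
            # phase B: joint 4-D proposals shaped by each subject's own
            # posterior covariance (captures e.g. the alpha-delta-tau ridge)
            for _rep in range(3):
                eps = rng.standard_normal((S, 4))
                step = np.einsum("sij,sj->si", prop_chol, eps)
                Zp = Z + lam[:, None] * step
                llp = problem.loglik(Zp)
                dprior = np.sum(
                    (-(Zp - cell_mean) ** 2 + (Z - cell_mean) ** 2)
                    / (2.0 * sd[None, :] ** 2), axis=1)
                accept = np.log(rng.random(S)) < (llp - ll) + dprior
                Z[accept] = Zp[accept]
                ll = np.where(accept, llp, ll)
                if adapting:
                    lam *= np.exp(rate * (accept.astype(float) - 0.23))
                    np.clip(lam, 0.05, 5.0, out=lam)
        if adapting and it >= phase_a_end // 2:
            # moments start after the initial transient so early drift does
            # not inflate the proposal covariance
            warm_count += 1
            d = Z - run_mean
            run_mean += d / warm_count
            run_m2 += np.einsum("si,sj->sij", d, Z - run_mean)
            if it >= phase_a_end and warm_count > 25 and (
                    it % 25 == 0 or it == config.n_warmup - 1):
                cov = run_m2 / max(warm_count - 1, 1)
                cov = cov + 1e-5 * np.eye(4)[None, :, :]
                prop_chol = np.linalg.cholesky((2.38 ** 2 / 4.0) * cov)
        # conjugate update of the group coefficients, one diffusion
        # parameter at a time: N(0,1) prior x normal likelihood
        for j in range(4):
            prec = XtX / sd[j] ** 2 + np.eye(4)
            rhs = X.T @ Z[:, j] / sd[j] ** 2
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            B[:, j] = mean + np.linalg.solve(L.T, rng.standard_normal(4))
        cell_mean = X @ B
        for j in range(4):
            ssr = float(np.sum((Z[:, j] - cell_mean[:, j]) ** 2))
            log_s[j] = _slice_sample_log_sd(log_s[j], ssr, S, rng)
        # group moves along the posterior ridges of the centered
        # parameterization: translate each coefficient together with the
        # subjects it governs (residuals unchanged), and rescale the
        # subject spread jointly with its SD
        sd = np.exp(log_s)
        cell_mean = X @ B
        for j in range(4):
            for e in range(4):
                shift = move_scales[e, j] * rng.standard_normal()
                Zp = Z.copy()
                Zp[:, j] = Z[:, j] + shift * X[:, e]
                llp = problem.loglik(Zp)
                d_prior = (B[e, j] ** 2 - (B[e, j] + shift) ** 2) / 2.0
                ok = math.log(rng.random()) < float(llp.sum() - ll.sum()) \
                    + d_prior
                if ok:
                    Z, ll = Zp, llp
                    B[e, j] += shift
                    cell_mean[:, j] += shift * X[:, e]
                if adapting:
                    move_scales[e, j] *= math.exp(rate * (float(ok) - 0.3))

            eps = move_scales[4, j] * rng.standard_normal()
            c = math.exp(eps)
            Zp = Z.copy()
            Zp[:, j] = cell_mean[:, j] + c * (Z[:, j] - cell_mean[:, j])
            llp = problem.loglik(Zp)
            # prior-on-sd change + net Jacobian of the (Z_j, s_j) map
            log_acc = (float(llp.sum() - ll.sum())
                       - (c ** 2 - 1.0) * sd[j] ** 2 / 2.0 + eps)
            ok = math.log(rng.random()) < log_acc
            if ok:
                Z, ll = Zp, llp
                log_s[j] += eps
                sd[j] *= c
            if adapting:
                move_scales[4, j] *= math.exp(rate * (float(ok) - 0.3))
        np.clip(move_scales, 1e-3, 2.0, out=move_scales)
        if not adapting:
            idx = it - config.n_warmup
            kept_group[idx, :16] = B.T.ravel()   # param-major: alpha mu..int
            kept_group[idx, 16:] = np.exp(log_s)
            subj_sum += np.column_stack(problem.natural(Z))
    return kept_group, subj_sum / n_keep


def fit_hierarchical_ddm(dataset: ChoiceDataset,
                         config: MCMCConfig | None = None) -> DDMPosterior:
    """Fit the hierarchical DDM with sex x condition group regressors.

    Skipped trials and trials faster than ``config.rt_floor`` (0.3 s) are
    excluded; every sex x condition cell needs at least two participants.
    Returns draws, R-hat and 95% HDIs for the 20 group-level scalars (4
    diffusion parameters x {grand mean, sex, condition, interaction,
    subject SD}) plus per-participant posterior-mean parameters. The
    result is flagged unconverged if any group-level R-hat is >= 1.01.
    """
    config = config or MCMCConfig()
    if config.seed is None:
        raise ValueError("MCMCConfig.seed is required")
    problem = _Problem(dataset, config)
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    group_draws = []
    subj_means = []
    for c in range(config.chains):
        kept, subj = _run_chain(problem, config, np.random.default_rng(seeds[c]))
        group_draws.append(kept)
        subj_means.append(subj)
    stacked = np.stack(group_draws)        # (chains, draws, 20)

    names = [f"{p}_{e}" for p in PARAMS for e in EFFECTS]
    names += [f"{p}_subject_sd" for p in PARAMS]
    draws = {nm: stacked[:, :, i] for i, nm in enumerate(names)}
    rhats = {nm: rhat(d) for nm, d in draws.items()}
    hdis = {nm: hdi(d.ravel()) for nm, d in draws.items()}
    converged = all(v < 1.01 for v in rhats.values())

    subj = np.mean(subj_means, axis=0)
    cells = (dataset.scored(config.rt_floor)
             .groupby("participant_id", sort=False)[["sex", "condition"]]
             .first().loc[problem.pids])
    subject_summary = pd.DataFrame(
        {"participant_id": problem.pids,
         "sex": cells["sex"].to_numpy(),
         "condition": cells["condition"].to_numpy(),
         "alpha": subj[:, 0], "beta": subj[:, 1],
         "delta": subj[:, 2], "tau": subj[:, 3]})
    return DDMPosterior(draws=draws, rhat=rhats, hdi_95=hdis,
                        subject_summary=subject_summary,
                        converged=converged, config=config)
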