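"""Between-subject design statistics.

Two-way ANOVA with Type II sums of squares and generalized eta squared,
one-sample t-tests with Cohen's d, and a-priori power / sample-size
computation for a fixed-effects ANOVA contrast via the noncentral F
distribution (noncentrality lambda = f^2 N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = ["AnovaTable", "PowerSpec", "two_way_anova", "one_sample_t",
           "cohen_d_from_t", "anova_power", "required_n",
           "exclude_perfect_discriminators"]


@dataclass
class AnovaTable:
    """Two-way between-subject ANOVA results (Type II SS).

    ``table`` rows: factor A, factor B, interaction, residual, with sum
    of squares, df, F, p and generalized eta squared (which equals
    partial eta squared in a purely between-subject design).
    """

    table: pd.DataFrame
    factor_a: str
    factor_b: str
    flags: list

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power specification for one ANOVA effect.

    effect_size_f: Cohen's f; numerator_df: the tested effect's df;
    n_groups: number of cells (error df = N - n_groups).
    """

    effect_size_f: float
    alpha: float = 0.05
    target_power: float = 0.80
    numerator_df: int = 1
    n_groups: int = 4

    def __post_init__(self) -> None:
        if not self.effect_size_f > 0:
            raise ValueError("effect_size_f must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must lie in (0, 1)")
        if self.n_groups < 2 or self.numerator_df < 1:
            raise ValueError("need n_groups >= 2 and numerator_df >= 1")


def two_way_anova(values, factor_a_labels, factor_b_labels,
                  factor_a: str = "A", factor_b: str = "B") -> AnovaTable:
    """Between-subject two-way ANOVA with Type II SS (unbalanced-safe).

    Generalized eta squared per effect is SS_effect / (SS_effect +
    SS_residual). A constant response leaves F undefined; the table is
    returned with zero effect SS and a 'constant_response' flag.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "fa": list(factor_a_labels),
                       "fb": list(factor_b_labels)})
    if df.isna().any().any():
        df = df.dropna()
    cell_counts = df.groupby(["fa", "fb"]).size()
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    if cell_counts.min() < 2 or len(cell_counts) < (
            df["fa"].nunique() * df["fb"].nunique()):
        raise ValueError("every cell needs >= 2 observations")

    flags: list = []
    if np.allclose(df["y"], df["y"].iloc[0]):
        idx = [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"]
        table = pd.DataFrame({"sum_sq": 0.0, "df": [1, 1, 1,
                                                    len(df) - 4],
                              "F": np.nan, "p": np.nan, "ges": np.nan},
                             index=idx)
        return AnovaTable(table, factor_a, factor_b, ["constant_response"])

    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_res = float(aov.loc["Residual", "sum_sq"])
    rename = {"C(fa)": factor_a, "C(fb)": factor_b,
              "C(fa):C(fb)": f"{factor_a}:{factor_b}",
              "Residual": "residual"}
    aov = aov.rename(index=rename)
    aov["ges"] = aov["sum_sq"] / (aov["sum_sq"] + ss_res)
    aov.loc["residual", "ges"] = np.nan
    table = aov.rename(columns={"PR(>F)": "p"})[
        ["sum_sq", "df", "F", "p", "ges"]]
    return AnovaTable(table, factor_a, factor_b, flags)


def one_sample_t(values, mu0: float) -> tuple[float, int, float, float]:
    """Two-sided one-sample t-test; returns (t, df, p, Cohen's d).

    d = (mean - mu0) / sd = t / sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.isclose(x.std(ddof=1), 0.0):
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu0)
    t = float(res.statistic)
    n = x.size
    return t, n - 1, float(res.pvalue), t / math.sqrt(n)


def cohen_d_from_t(t: float, n: int) -> float:
    """One-sample Cohen's d implied by a t statistic: d = t / sqrt(n)."""
    return t / math.sqrt(n)


def anova_power(spec: PowerSpec, total_n: int) -> float:
    """Power of the noncentral-F test at total sample size ``total_n``.

    The tested statistic is F(numerator_df, N - n_groups) with
    noncentrality lambda = f^2 N; power is the probability it exceeds
    the central-F critical value at the spec's alpha.
    """
    df2 = total_n - spec.n_groups
    if df2 < 1:
        raise ValueError("total_n must exceed n_groups")
    lam = spec.effect_size_f ** 2 * total_n
    fcrit = stats.f.isf(spec.alpha, spec.numerator_df, df2)
    return float(stats.ncf.sf(fcrit, spec.numerator_df, df2, lam))


def required_n(spec: PowerSpec, n_max: int = 10 ** 6) -> int:
    """Smallest total N whose a-priori power reaches the target."""
    n = spec.n_groups + max(2, spec.numerator_df + 1)
    while n <= n_max:
        if anova_power(spec, n) >= spec.target_power:
            return n
        n += 1
    raise ValueError(f"target power not reachable with N <= {n_max}")


def exclude_perfect_discriminators(correct_counts, n_trials: int = 6
                                   ) -> np.ndarray:
    """Screening mask for the triangle odour discrimination task.

    Participants who identify the odd stimulus on *all* ``n_trials``
    trials are excluded (True = keep), since perfect discrimination of
    the active stimulus could confound a blinded exposure manipulation.
    """
    counts = np.asarray(correct_counts)
    if np.any((counts < 0) | (counts > n_trials)):
        raise ValueError("counts must lie in [0, n_trials]")
    return counts < n_trials
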