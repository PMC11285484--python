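"""Task structure for the social discounting paradigm.

The task presents repeated choices between a *selfish* option (a variable
amount of money for the participant alone) and a *generous* option (a fixed
amount for both the participant and a person at a stated social distance).
The default :class:`TaskDesign` encodes the standard layout: 8 social
distances crossed with 9 selfish amounts (130-290 HKD in 20 HKD steps),
a 130 HKD generous amount, a 6 s response window, and a 105 HKD flat fee
plus 5% of the chosen amount paid out from one randomly selected trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TaskDesign", "build_trial_grid", "UPPER_BOUNDARY_CHOICE"]

#: Which choice the *upper* diffusion boundary maps to. The generative and
#: fitting code share this constant so simulated data and the likelihood
#: agree. Configurable per-call where it matters.
UPPER_BOUNDARY_CHOICE = "selfish"

DEFAULT_DISTANCES = (1, 2, 3, 5, 10, 20, 50, 100)
DEFAULT_AMOUNTS = tuple(range(130, 291, 20))


@dataclass(frozen=True)
class TaskDesign:
    """Constants of the social discounting task.

    Parameters
    ----------
    distances
        Ordered social-distance ranks (1 = closest person, 100 = stranger).
    selfish_amounts
        Ordered selfish-option amounts in HKD; the smallest equals the
        generous amount so the selfish option always weakly dominates in
        money to self.
    generous_amount
        Amount (HKD) that both the participant and the partner receive
        under the generous option.
    response_window
        Maximum response time in seconds; slower trials are skipped.
    iti
        Inter-trial interval in seconds (bookkeeping only).
    rt_floor
        Fast-guess threshold in seconds; trials faster than this are
        excluded from likelihood-based fits.
    flat_fee
        Show-up fee in HKD.
    payout_rate
        Fraction of the chosen amount(s) on one randomly drawn trial that
        is actually paid out.
    """

    distances: Sequence[int] = DEFAULT_DISTANCES
    selfish_amounts: Sequence[float] = DEFAULT_AMOUNTS
    generous_amount: float = 130.0
    response_window: float = 6.0
    iti: float = 1.0
    rt_floor: float = 0.3
    flat_fee: float = 105.0
    payout_rate: float = 0.05

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        a = np.asarray(self.selfish_amounts, dtype=float)
        if d.size == 0 or a.size == 0:
            raise ValueError("distances and selfish_amounts must be non-empty")
        if not (np.all(np.diff(d) > 0) and d.min() >= 1):
            raise ValueError("distances must be strictly increasing and >= 1")
        if not np.all(np.diff(a) > 0):
            raise ValueError("selfish_amounts must be strictly increasing")
        if a.min() < self.generous_amount:
            raise ValueError(
                "smallest selfish amount must be >= generous_amount"
            )
        if not self.rt_floor < self.response_window:
            raise ValueError("rt_floor must be below the response window")
        if not 0.0 < self.payout_rate < 1.0:
            raise ValueError("payout_rate must lie in (0, 1)")
        object.__setattr__(self, "distances", tuple(int(x) for x in d))
        object.__setattr__(self, "selfish_amounts", tuple(float(x) for x in a))

    @property
    def n_trials(self) -> int:
        return len(self.distances) * len(self.selfish_amounts)

    @property
    def max_forgone(self) -> float:
        """Theoretical maximum amount forgone (HKD): the imputed ceiling
        indifference point minus the generous amount."""
        return self.imputed_high - self.generous_amount

    @property
    def _half_increment(self) -> float:
        amts = self.selfish_amounts
        if len(amts) < 2:
            return 10.0
        return (amts[1] - amts[0]) / 2.0

    @property
    def imputed_low(self) -> float:
        """Indifference point imputed when a participant is always selfish:
        half an increment below the smallest selfish amount."""
        return self.selfish_amounts[0] - self._half_increment

    @property
    def imputed_high(self) -> float:
        """Indifference point imputed when a participant is always generous:
        half an increment above the largest selfish amount."""
        return self.selfish_amounts[-1] + self._half_increment

    def payout(self, chosen_amount: float) -> float:
        """Participant's total compensation if the randomly drawn trial paid
        ``chosen_amount`` to the participant."""
        return self.flat_fee + self.payout_rate * chosen_amount

    @property
    def min_payout(self) -> float:
        """Smallest possible total compensation: flat fee plus the payout
        fraction of the generous (smallest) own-amount."""
        return self.payout(self.generous_amount)

    @property
    def max_payout(self) -> float:
        return self.payout(self.selfish_amounts[-1])


def build_trial_grid(
    design: TaskDesign,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """Full factorial trial list: every (distance, selfish amount) pair once.

    With ``rng`` supplied, the distance blocks are shuffled and the trials
    within each block are shuffled, mirroring the task's randomization;
    without it the grid is in canonical sorted order.
    """
    distances = list(design.distances)
    amounts = list(design.selfish_amounts)
    if rng is not None:
        distances = [distances[i] for i in rng.permutation(len(distances))]
    grid: list[tuple[int, float]] = []
    for d in distances:
        block = list(amounts)
        if rng is not None:
            block = [block[i] for i in rng.permutation(len(block))]
        grid.extend((d, a) for a in block)
    return grid
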