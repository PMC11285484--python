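"""Reading and writing long-format behavioural trial tables.

One row per trial with columns
``participant_id,sex,condition,distance,selfish_amount,choice,rt``.
Money is carried in HKD with one decimal place, response times in seconds
with three decimals; a skipped trial has an empty ``rt`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TaskDesign

__all__ = ["TrialRecord", "ChoiceDataset", "read_trials", "write_trials",
           "TrialValidationError"]

SEXES = ("female", "male")
CONDITIONS = ("androstadienone", "control")
CHOICES = ("selfish", "generous", "skipped")

COLUMNS = ["participant_id", "sex", "condition", "distance",
           "selfish_amount", "choice", "rt"]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema; names the line."""


@dataclass(frozen=True)
class TrialRecord:
    """A single scored or skipped trial."""

    participant_id: str
    sex: str
    condition: str
    distance: int
    selfish_amount: float
    choice: str
    rt: float | None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.choice not in CHOICES:
            raise ValueError(f"unknown choice {self.choice!r}")
        if self.choice == "skipped":
            if self.rt is not None:
                raise ValueError("skipped trial must not carry an rt")
        else:
            if self.rt is None or not self.rt > 0:
                raise ValueError("scored trial requires rt > 0")


@dataclass
class ChoiceDataset:
    """A cohort of trials as a typed long-format table.

    ``trials`` has the canonical columns; ``design`` carries the task
    constants the trials were generated or collected under.
    """

    trials: pd.DataFrame
    design: TaskDesign = field(default_factory=TaskDesign)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.trials.columns]
        if missing:
            raise TrialValidationError(f"missing columns: {missing}")
        self.trials = self.trials[COLUMNS].reset_index(drop=True)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.trials["participant_id"]))

    def scored(self, rt_floor: float | None = None) -> pd.DataFrame:
        """Non-skipped trials, optionally dropping fast guesses
        (rt < ``rt_floor`` seconds)."""
        out = self.trials[self.trials["choice"] != "skipped"]
        if rt_floor is not None:
            out = out[out["rt"] >= rt_floor]
        return out

    def participant_cells(self) -> pd.DataFrame:
        """One row per participant with its sex and condition labels."""
        return (self.trials.groupby("participant_id", sort=False)
                [["sex", "condition"]].first().reset_index())

    def to_records(self) -> list[TrialRecord]:
        recs = []
        for row in self.trials.itertuples(index=False):
            rt = None if pd.isna(row.rt) else float(row.rt)
            recs.append(TrialRecord(str(row.participant_id), row.sex,
                                    row.condition, int(row.distance),
                                    float(row.selfish_amount), row.choice, rt))
        return recs


def write_trials(dataset: ChoiceDataset, path: str | Path) -> None:
    """Write the trial table as CSV (empty rt field on skipped trials)."""
    df = dataset.trials.copy()
    df["selfish_amount"] = df["selfish_amount"].map(lambda v: f"{v:.1f}")
    df["rt"] = df["rt"].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    df.to_csv(path, index=False)


def read_trials(path: str | Path, design: TaskDesign | None = None) -> ChoiceDataset:
    """Read and validate a long-format trial CSV.

    Malformed rows are rejected with their (1-based, header-inclusive)
    line number; category vocabularies and the rt/skipped invariant are
    enforced.
    """
    design = design or TaskDesign()
    df = pd.read_csv(path, dtype={"participant_id": str, "sex": str,
                                  "condition": str, "choice": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing columns {missing}")

    def _bad(idx: int, msg: str) -> TrialValidationError:
        return TrialValidationError(f"{path}: line {idx + 2}: {msg}")

    for col, vocab in [("sex", SEXES), ("condition", CONDITIONS),
                       ("choice", CHOICES)]:
        bad = ~df[col].isin(vocab)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise _bad(i, f"unknown {col} label {df[col].iloc[i]!r}")

    skipped = df["choice"] == "skipped"
    has_rt = df["rt"].notna()
    if (skipped & has_rt).any():
        i = int(np.flatnonzero(skipped & has_rt)[0])
        raise _bad(i, "numeric rt on a skipped trial")
    if (~skipped & ~has_rt).any():
        i = int(np.flatnonzero(~skipped & ~has_rt)[0])
        raise _bad(i, "missing rt on a scored trial")
    scored_rt = df.loc[~skipped, "rt"].astype(float)
    out_of_range = (scored_rt <= 0) | (scored_rt > design.response_window)
    if out_of_range.any():
        i = int(out_of_range[out_of_range].index[0])
        raise _bad(i, f"rt outside (0, {design.response_window}]")

    df["distance"] = df["distance"].astype(int)
    df["selfish_amount"] = df["selfish_amount"].astype(float)
    df["rt"] = df["rt"].astype(float)
    return ChoiceDataset(df, design)
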