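"""Fixed intertemporal-choice trial menus.

Every subject in a study sees the same menu of 120 choices between an
immediate reward (fixed at 10,000 KRW) and a larger delayed reward
(11,000-48,000 KRW at 2-180 days), so fitted discount rates are directly
comparable across subjects.  This module defines that menu as data:
generation of a default factorial grid, validation, and CSV round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

IMMEDIATE_AMOUNT = 10_000
AMOUNT_BOUNDS = (11_000, 48_000)
DELAY_BOUNDS = (2, 180)
N_TRIALS_DEFAULT = 120

TRIAL_COLUMNS = ["trial_id", "immediate_amount", "delayed_amount", "delay_days"]


class TrialValidationError(ValueError):
    """A trial table violates the task-design invariants."""


@dataclass(frozen=True)
class Trial:
    trial_id: int
    immediate_amount: int
    delayed_amount: int
    delay_days: int

    def validate(self) -> None:
        if self.immediate_amount != IMMEDIATE_AMOUNT:
            raise TrialValidationError(
                f"trial {self.trial_id}: immediate_amount must be "
                f"{IMMEDIATE_AMOUNT}, got {self.immediate_amount}"
            )
        if not AMOUNT_BOUNDS[0] <= self.delayed_amount <= AMOUNT_BOUNDS[1]:
            raise TrialValidationError(
                f"trial {self.trial_id}: delayed_amount {self.delayed_amount} "
                f"outside {AMOUNT_BOUNDS}"
            )
        if self.delayed_amount <= self.immediate_amount:
            raise TrialValidationError(
                f"trial {self.trial_id}: delayed_amount must exceed the "
                f"immediate amount"
            )
        if not DELAY_BOUNDS[0] <= self.delay_days <= DELAY_BOUNDS[1]:
            raise TrialValidationError(
                f"trial {self.trial_id}: delay_days {self.delay_days} "
                f"outside {DELAY_BOUNDS}"
            )


@dataclass(frozen=True)
class TrialSet:
    """An ordered, validated menu of intertemporal choices."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if sorted(ids) != list(range(1, len(self.trials) + 1)):
            raise TrialValidationError(
                "trial_ids must be unique and contiguous starting at 1"
            )
        for t in self.trials:
            t.validate()

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def delayed_amounts(self) -> np.ndarray:
        return np.array([t.delayed_amount for t in self.trials], dtype=float)

    @property
    def delays(self) -> np.ndarray:
        return np.array([t.delay_days for t in self.trials], dtype=float)

    @property
    def immediate_amounts(self) -> np.ndarray:
        return np.array([t.immediate_amount for t in self.trials], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "immediate_amount": [t.immediate_amount for t in self.trials],
                "delayed_amount": [t.delayed_amount for t in self.trials],
                "delay_days": [t.delay_days for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialSet":
        missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
        if missing:
            raise TrialValidationError(f"missing columns: {missing}")
        for col in TRIAL_COLUMNS:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any():
                row = int(frame.index[coerced.isna()][0])
                raise TrialValidationError(
                    f"non-numeric value in column {col!r} at row {row}"
                )
        ids = frame["trial_id"].astype(int)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise TrialValidationError(
                f"duplicate trial_id values: {sorted(set(dup))}"
            )
        trials = tuple(
            Trial(
                trial_id=int(r.trial_id),
                immediate_amount=int(r.immediate_amount),
                delayed_amount=int(r.delayed_amount),
                delay_days=int(r.delay_days),
            )
            for r in frame.sort_values("trial_id").itertuples()
        )
        return cls(trials)


def _log_spaced_integer_delays(
    n: int, delay_range: tuple[int, int]
) -> np.ndarray:
    """Approximately log-spaced integer delays, deduplicated then padded.

    Rounding a geometric progression to integers can collide at the short
    end; collisions are replaced by the smallest unused integers in range so
    the requested count is preserved.
    """
    lo, hi = delay_range
    raw = np.geomspace(lo, hi, n)
    days = sorted(set(int(round(d)) for d in raw))
    candidates = (d for d in range(lo, hi + 1) if d not in days)
    while len(days) < n:
        days.append(next(candidates))
    return np.array(sorted(days), dtype=int)


def generate_trial_set(
    n_amounts: int = 12,
    n_delays: int = 10,
    amount_range: tuple[int, int] = AMOUNT_BOUNDS,
    delay_range: tuple[int, int] = DELAY_BOUNDS,
    n_trials: int = N_TRIALS_DEFAULT,
) -> TrialSet:
    """Build a factorial amount x delay menu.

    Amounts are evenly spaced (rounded to whole KRW) over ``amount_range``;
    delays are approximately log-spaced integers over ``delay_range``.  The
    grid is deterministic: two calls with the same arguments are identical.
    """
    if n_amounts < 1 or n_delays < 1:
        raise TrialValidationError("grid dimensions must be >= 1")
    if n_amounts * n_delays != n_trials:
        raise TrialValidationError(
            f"n_amounts*n_delays = {n_amounts * n_delays} does not match the "
            f"requested trial count {n_trials}"
        )
    if not (AMOUNT_BOUNDS[0] <= amount_range[0] <= amount_range[1] <= AMOUNT_BOUNDS[1]):
        raise TrialValidationError(
            f"amount_range {amount_range} outside task bounds {AMOUNT_BOUNDS}"
        )
    if not (DELAY_BOUNDS[0] <= delay_range[0] <= delay_range[1] <= DELAY_BOUNDS[1]):
        raise TrialValidationError(
            f"delay_range {delay_range} outside task bounds {DELAY_BOUNDS}"
        )
    amounts = np.round(np.linspace(amount_range[0], amount_range[1], n_amounts))
    delays = _log_spaced_integer_delays(n_delays, delay_range)
    trials = []
    tid = 1
    for a in amounts.astype(int):
        for d in delays:
            trials.append(
                Trial(
                    trial_id=tid,
                    immediate_amount=IMMEDIATE_AMOUNT,
                    delayed_amount=int(a),
                    delay_days=int(d),
                )
            )
            tid += 1
    return TrialSet(tuple(trials))


def write_trials(trial_set: TrialSet, path: str | Path) -> None:
    trial_set.to_frame().to_csv(path, index=False)


def read_trials(path: str | Path, expected_count: int | None = None) -> TrialSet:
    frame = pd.read_csv(path)
    ts = TrialSet.from_frame(frame)
    if expected_count is not None and len(ts) != expected_count:
        raise TrialValidationError(
            f"{path}: expected {expected_count} trials, found {len(ts)}"
        )
    return ts
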