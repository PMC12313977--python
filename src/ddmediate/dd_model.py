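"""Hyperbolic delay discounting with a logistic choice rule.

The subjective value of a reward of amount ``A`` delivered after ``D`` days
is ``SV = A / (1 + k*D)`` where ``k`` (per day) is the subject's discount
rate.  On each trial the probability of taking the delayed option follows a
logistic function of the subjective-value difference,

    P(delayed) = 1 / (1 + exp(-beta * (SV_delayed - SV_immediate))),

with ``beta`` an inverse-temperature scaling fitted per subject.  Because
amounts are on a KRW scale (thousands of won), plausible ``beta`` values are
small.  ``fit_subject`` estimates (k, beta) jointly by maximum likelihood
over a Bernoulli model of the binary choices, optimising in log10 space with
a deterministic multi-start grid.  Discount rates are reported as log10(k),
which normalises the typically right-skewed k distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task import TrialSet

#: Floor applied to choice probabilities inside logarithms.
PROB_EPS = 1e-12


class ChoiceDataError(ValueError):
    pass


@dataclass(frozen=True)
class ChoiceData:
    """One subject's binary decisions, aligned to a :class:`TrialSet`.

    ``choices[t] == 1`` means the delayed option was taken on trial ``t``.
    """

    subject_id: str
    choices: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.choices)
        if arr.ndim != 1:
            raise ChoiceDataError("choices must be one-dimensional")
        if np.isnan(arr.astype(float)).any():
            raise ChoiceDataError(
                f"subject {self.subject_id}: missing choice entries"
            )
        if not np.isin(arr, (0, 1)).all():
            raise ChoiceDataError(
                f"subject {self.subject_id}: choices must be 0 or 1"
            )
        object.__setattr__(self, "choices", arr.astype(np.int8))

    def __len__(self) -> int:
        return len(self.choices)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings for per-subject maximum likelihood.

    Bounds are in log10 units: k in [1e-5, 1] per day, beta in [1e-6, 1]
    (beta multiplies KRW-scale value differences, so useful values are
    small).  A deterministic ``n_grid`` x ``n_grid`` log-spaced grid of
    starting points precedes local refinement; no randomness enters fitting.
    """

    log10_k_bounds: tuple[float, float] = (-5.0, 0.0)
    log10_beta_bounds: tuple[float, float] = (-6.0, 0.0)
    n_grid: int = 7
    n_refine: int = 3
    boundary_tol: float = 1e-3
    prob_eps: float = PROB_EPS


@dataclass(frozen=True)
class DDParams:
    subject_id: str
    k: float
    beta: float
    log10_k: float
    nll: float
    converged: bool
    boundary_flag: str = "none"  # none | k_low | k_high | beta_low | beta_high

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError("k must be finite and positive")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError("beta must be finite and positive")
        if abs(self.log10_k - np.log10(self.k)) > 1e-12:
            raise ValueError("log10_k inconsistent with k")


def subjective_value(amount, delay, k):
    """Hyperbolically discounted value ``A / (1 + k*D)``.

    Equals ``A`` at zero delay or zero discount rate; strictly decreasing in
    both delay and ``k`` otherwise.  Accepts scalars or arrays.
    """
    amount = np.asarray(amount, dtype=float)
    delay = np.asarray(delay, dtype=float)
    k = np.asarray(k, dtype=float)
    if (amount <= 0).any() if amount.ndim else amount <= 0:
        raise ValueError("amount must be positive")
    if (delay < 0).any() if delay.ndim else delay < 0:
        raise ValueError("delay must be non-negative")
    if (k < 0).any() if k.ndim else k < 0:
        raise ValueError("k must be non-negative")
    return amount / (1.0 + k * delay)


def choice_probability(sv_delayed, sv_immediate, beta):
    """Probability of choosing the delayed option under the logistic rule."""
    beta = np.asarray(beta, dtype=float)
    if (beta < 0).any() if beta.ndim else beta < 0:
        raise ValueError("beta must be non-negative")
    diff = np.asarray(sv_delayed, dtype=float) - np.asarray(sv_immediate, dtype=float)
    # expit, written out to keep the clipping explicit
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-beta * diff))
    return p


def negative_log_likelihood(
    k: float,
    beta: float,
    data: ChoiceData,
    trials: TrialSet,
    prob_eps: float = PROB_EPS,
) -> float:
    """Bernoulli negative log-likelihood of one subject's choices.

    Probabilities are clipped to ``[prob_eps, 1 - prob_eps]`` before the
    logarithm so deterministic responders yield a finite value.
    """
    choices = data.choices
    if len(choices) != len(trials):
        raise ChoiceDataError(
            f"choices length {len(choices)} does not match trial set "
            f"length {len(trials)}"
        )
    sv_d = subjective_value(trials.delayed_amounts, trials.delays, k)
    sv_i = trials.immediate_amounts
    p1 = choice_probability(sv_d, sv_i, beta)
    p1 = np.clip(p1, prob_eps, 1.0 - prob_eps)
    ll = np.where(choices == 1, np.log(p1), np.log1p(-p1))
    return float(-np.sum(ll))


def _nll_log10(theta: np.ndarray, choices: np.ndarray, sv_parts, prob_eps: float) -> float:
    """NLL parametrised by (log10 k, log10 beta); used by the optimiser."""
    amounts, delays, immediates = sv_parts
    k = 10.0 ** theta[0]
    beta = 10.0 ** theta[1]
    sv_d = amounts / (1.0 + k * delays)
    with np.errstate(over="ignore"):
        p1 = 1.0 / (1.0 + np.exp(-beta * (sv_d - immediates)))
    p1 = np.clip(p1, prob_eps, 1.0 - prob_eps)
    ll = np.where(choices == 1, np.log(p1), np.log1p(-p1))
    return float(-np.sum(ll))


def _boundary_flag(theta: np.ndarray, config: FitConfig) -> str:
    kb, bb = config.log10_k_bounds, config.log10_beta_bounds
    tol = config.boundary_tol
    if theta[0] <= kb[0] + tol:
        return "k_low"
    if theta[0] >= kb[1] - tol:
        return "k_high"
    if theta[1] <= bb[0] + tol:
        return "beta_low"
    if theta[1] >= bb[1] - tol:
        return "beta_high"
    return "none"


def fit_subject(
    data: ChoiceData, trials: TrialSet, config: FitConfig = FitConfig()
) -> DDParams:
    """Joint maximum-likelihood estimate of (k, beta) for one subject.

    A log-spaced coarse grid of starting points is evaluated, the best
    ``config.n_refine`` are refined with bounded L-BFGS-B, and the overall
    minimum is returned.  Near-degenerate choosers (e.g. all-immediate) have
    no interior optimum in k; the fit then lands on a bound and the
    ``boundary_flag`` records which.  The whole procedure is deterministic.
    """
    if len(data) != len(trials):
        raise ChoiceDataError(
            f"choices length {len(data)} does not match trial set length "
            f"{len(trials)}"
        )
    choices = data.choices
    sv_parts = (trials.delayed_amounts, trials.delays, trials.immediate_amounts)
    kb, bb = config.log10_k_bounds, config.log10_beta_bounds
    k_starts = np.linspace(kb[0], kb[1], config.n_grid)
    b_starts = np.linspace(bb[0], bb[1], config.n_grid)
    grid = [
        (np.array([lk, lb]), _nll_log10(np.array([lk, lb]), choices, sv_parts, config.prob_eps))
        for lk in k_starts
        for lb in b_starts
    ]
    grid.sort(key=lambda t: t[1])

    best_theta, best_nll, converged = grid[0][0], grid[0][1], False
    for theta0, _ in grid[: config.n_refine]:
        res = minimize(
            _nll_log10,
            theta0,
            args=(choices, sv_parts, config.prob_eps),
            method="L-BFGS-B",
            bounds=[kb, bb],
        )
        if res.fun < best_nll - 1e-12 or (res.success and res.fun <= best_nll):
            best_theta, best_nll = np.asarray(res.x), float(res.fun)
            converged = converged or bool(res.success)

    # Saturation: degenerate choosers (all-immediate, all-delayed, or fully
    # model-consistent) leave the likelihood flat on a plateau that extends
    # to one or more search bounds, and the optimiser stops at an arbitrary
    # plateau point.  Push each coordinate to a bound when that costs
    # nothing, so the boundary flag records the degeneracy; k is tried
    # first so all-immediate/all-delayed report a k flag.
    for coord, bound in ((0, kb[0]), (0, kb[1]), (1, bb[1])):
        theta_sat = best_theta.copy()
        theta_sat[coord] = bound
        nll_sat = _nll_log10(theta_sat, choices, sv_parts, config.prob_eps)
        if nll_sat <= best_nll + 1e-9:
            best_theta, best_nll = theta_sat, min(best_nll, nll_sat)
            break

    flag = _boundary_flag(best_theta, config)
    k = float(10.0 ** best_theta[0])
    beta = float(10.0 ** best_theta[1])
    return DDParams(
        subject_id=data.subject_id,
        k=k,
        beta=beta,
        log10_k=float(np.log10(k)),
        nll=best_nll,
        converged=converged,
        boundary_flag=flag,
    )


def fit_cohort(
    choice_data: Iterable[ChoiceData],
    trials: TrialSet,
    config: FitConfig = FitConfig(),
) -> pd.DataFrame:
    """Fit every subject; one row per subject in input order."""
    rows = []
    for data in choice_data:
        p = fit_subject(data, trials, config)
        rows.append(
            {
                "subject_id": p.subject_id,
                "k": p.k,
                "log10_k": p.log10_k,
                "beta": p.beta,
                "nll": p.nll,
                "converged": p.converged,
                "boundary_flag": p.boundary_flag,
            }
        )
    return pd.DataFrame(rows)


def k_identified(fits: pd.DataFrame) -> pd.Series:
    """Mask of subjects whose discount rate is identified by the task.

    A fit pinned at a k search bound (flag ``k_low``/``k_high``) means the
    subject's choices carry no information about k inside the menu's
    discriminable range (e.g. an all-delayed chooser); such estimates are
    excluded from downstream inference.  A ``beta_high`` flag does not
    disqualify a subject: a fully model-consistent responder has a
    saturated choice rule but a well-identified discount rate.
    """
    return ~fits["boundary_flag"].isin(("k_low", "k_high"))


def read_choices(path: str | Path, trials: TrialSet) -> list[ChoiceData]:
    """Read long-format choices (subject_id,trial_id,choice) as ChoiceData.

    Rows are aligned to the trial set by trial_id; every subject must cover
    every trial exactly once.
    """
    frame = pd.read_csv(path)
    required = {"subject_id", "trial_id", "choice"}
    missing = required - set(frame.columns)
    if missing:
        raise ChoiceDataError(f"missing columns: {sorted(missing)}")
    expected_ids = [t.trial_id for t in trials.trials]
    out = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial_id")
        if list(grp["trial_id"]) != expected_ids:
            raise ChoiceDataError(
                f"subject {sid}: trial_ids do not match the trial set"
            )
        out.append(ChoiceData(subject_id=str(sid), choices=grp["choice"].to_numpy()))
    return out


def write_choices(choice_data: Iterable[ChoiceData], trials: TrialSet, path: str | Path) -> None:
    ids = [t.trial_id for t in trials.trials]
    frames = [
        pd.DataFrame(
            {"subject_id": cd.subject_id, "trial_id": ids, "choice": cd.choices}
        )
        for cd in choice_data
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
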