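"""Covariate-adjusted rank correlation and cohort descriptives.

The analysis question is whether an emotion-regulation subscale score
relates monotonically to temporal impulsivity (log10 discount rate) after
adjusting for demographics.  The partial Spearman correlation is computed
as rank-transform-then-residualise: x and y are converted to average ranks,
each is residualised on [intercept, covariates] by least squares, and the
Pearson correlation of the residuals is returned with a t-approximation
p-value on n - 2 - q degrees of freedom (q covariates).  An alternative
operationalisation (residualise raw values first, then Spearman of the
residuals) is available for sensitivity analysis, as is a permutation p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class PartialCorrelation:
    rho: float
    p_value: float
    n_effective: int
    n_covariates: int
    method: str


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        covs = design[:, 1:]
        constant = [
            int(j) for j in range(covs.shape[1]) if np.ptp(covs[:, j]) == 0
        ]
        pairs = []
        if covs.shape[1] > 1:
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(covs.T)
            dep = np.argwhere(np.abs(np.triu(corr, 1)) > 1 - 1e-10)
            pairs = [tuple(int(i) for i in p) for p in dep]
        detail = (
            f"constant columns {constant}" if constant
            else f"collinear column pairs {pairs}" if pairs
            else "dependency spans multiple columns"
        )
        raise AssociationError(
            f"covariate matrix is rank deficient (rank {rank} < "
            f"{design.shape[1]}); {detail} (0-based covariate indices)"
        )
    return v - design @ coef


def partial_spearman(
    x,
    y,
    covariates=None,
    method: str = "rank_then_residualize",
    permutations: int = 0,
    seed: int | None = None,
) -> PartialCorrelation:
    """Spearman correlation of x and y controlling for covariates.

    With no covariates this reduces exactly to the ordinary Spearman
    correlation.  ``method='residualize_then_rank'`` instead residualises
    the raw variables and takes the Spearman correlation of the residuals
    (a sensitivity variant).  If ``permutations > 0`` the returned p-value
    is a two-sided permutation p (requires ``seed``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("x and y must be equal-length vectors")
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise AssociationError("covariates must have one row per subject")
    q = C.shape[1]
    design = np.column_stack([np.ones(n), C])

    if method == "rank_then_residualize":
        rx = _residualize(stats.rankdata(x), design)
        ry = _residualize(stats.rankdata(y), design)
        rho = float(np.corrcoef(rx, ry)[0, 1])
    elif method == "residualize_then_rank":
        ex = _residualize(x, design)
        ey = _residualize(y, design)
        rho = float(stats.spearmanr(ex, ey).statistic)
    else:
        raise AssociationError(f"unknown method {method!r}")

    df = n - 2 - q
    if df <= 0:
        raise AssociationError("not enough observations for the covariate set")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / max(1.0 - rho**2, np.finfo(float).tiny))
    p = float(2 * stats.t.sf(abs(t), df))

    if permutations:
        if seed is None:
            raise AssociationError("permutation p-value requires a seed")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            r = partial_spearman(x[perm], y, C, method=method).rho
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (permutations + 1)

    return PartialCorrelation(
        rho=rho, p_value=p, n_effective=n, n_covariates=q, method=method
    )


DESCRIBE_COLUMNS = [
    "k",
    "log10_k",
    "reappraisal",
    "suppression",
    "age",
    "sex",
    "handedness",
    "education_years",
    "tiv",
]


def describe_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Means and SDs (n-1 denominator) of the analysis columns present."""
    if len(table) == 0:
        raise AssociationError("empty cohort table")
    cols = [c for c in DESCRIBE_COLUMNS if c in table.columns]
    out = pd.DataFrame(
        {
            "mean": table[cols].mean(),
            "sd": table[cols].std(ddof=1),
        }
    )
    out.index.name = "variable"
    return out
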