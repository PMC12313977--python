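"""Covariate-adjusted linear mediation with bootstrap inference.

Three ordinary least-squares regressions, all sharing the same covariate
set C, decompose the effect of an exposure X on an outcome Y through a
scalar mediator M:

    M ~ 1 + X + C          -> a      (X -> M)
    Y ~ 1 + X + M + C      -> c', b  (direct effect; M -> Y given X)
    Y ~ 1 + X + C          -> c      (total effect)

The indirect effect is a*b, and because the covariates are identical in
all three fits the exact algebraic identity c = c' + a*b holds on every
dataset.  Inference on the indirect effect uses a nonparametric case
bootstrap: subjects (whole rows) are resampled with replacement, all paths
are recomputed per resample, and the percentile interval and sign-based
two-sided p-value (with the (r+1)/(B+1) small-sample adjustment) are
reported.  A bias-corrected (BC) interval is available as a sensitivity
option.  All analyses are complete-case; rows with missing values in any
model variable are dropped before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_COVARIATES = ("age", "sex", "handedness", "education_years", "tiv")


class MediationError(ValueError):
    pass


@dataclass(frozen=True)
class MediationDesign:
    x_name: str = "reappraisal"
    m_name: str = "vs_gmv"
    y_name: str = "log10_k"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        roles = {self.x_name, self.m_name, self.y_name}
        if len(roles) != 3:
            raise MediationError("x, m, y must be three distinct columns")
        overlap = roles & set(self.covariates)
        if overlap:
            raise MediationError(
                f"covariates must exclude x/m/y, found {sorted(overlap)}"
            )

    def resolve(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [self.x_name, self.m_name, self.y_name, *self.covariates]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise MediationError(f"columns not in cohort table: {missing}")
        return table[cols].dropna()


@dataclass(frozen=True)
class PathEstimates:
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    se_a: float
    se_b: float
    se_c: float
    se_c_prime: float
    se_ab: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int


@dataclass(frozen=True)
class MediationResult:
    paths: PathEstimates
    ab_boot: np.ndarray = field(repr=False)
    ci_ab: tuple[float, float]
    ci_level: float
    p_ab: float
    p_a_boot: float
    p_b_boot: float
    p_c_boot: float
    p_c_prime_boot: float
    se_ab_boot: float
    n_boot: int
    seed: int
    ci_method: str
    n_redraws: int
    covariate_names: tuple[str, ...]


def _design_matrices(data: pd.DataFrame, design: MediationDesign):
    x = data[design.x_name].to_numpy(float)
    m = data[design.m_name].to_numpy(float)
    y = data[design.y_name].to_numpy(float)
    C = data[list(design.covariates)].to_numpy(float)
    n = len(x)
    ones = np.ones(n)
    Xm = np.column_stack([ones, x, C])          # M ~ 1 + X + C
    Xy_full = np.column_stack([ones, x, m, C])  # Y ~ 1 + X + M + C
    return x, m, y, C, Xm, Xy_full


def fit_paths(table: pd.DataFrame, design: MediationDesign) -> PathEstimates:
    """Point estimates and analytic (OLS) standard errors for all paths.

    The standard error of the indirect effect uses the first-order delta
    method, se(ab)^2 = a^2 se(b)^2 + b^2 se(a)^2 (Sobel); it is reported for
    reference but inference should rely on the bootstrap.
    """
    data = design.resolve(table)
    n = len(data)
    p_max = 3 + len(design.covariates)
    if n <= p_max:
        raise MediationError(f"n = {n} too small for {p_max} parameters")
    x, m, y, C, Xm, Xy_full = _design_matrices(data, design)

    def _ols(endog, exog, names):
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise MediationError(
                f"rank-deficient design; check columns {names}"
            )
        return sm.OLS(endog, exog).fit()

    names_m = ["const", design.x_name, *design.covariates]
    names_y = ["const", design.x_name, design.m_name, *design.covariates]
    fit_m = _ols(m, Xm, names_m)
    fit_y = _ols(y, Xy_full, names_y)
    fit_t = _ols(y, Xm, names_m)  # total-effect model reuses the M design

    a, se_a, p_a = fit_m.params[1], fit_m.bse[1], fit_m.pvalues[1]
    c_prime, se_cp, p_cp = fit_y.params[1], fit_y.bse[1], fit_y.pvalues[1]
    b, se_b, p_b = fit_y.params[2], fit_y.bse[2], fit_y.pvalues[2]
    c, se_c, p_c = fit_t.params[1], fit_t.bse[1], fit_t.pvalues[1]
    ab = a * b
    se_ab = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))

    return PathEstimates(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime), ab=float(ab),
        se_a=float(se_a), se_b=float(se_b), se_c=float(se_c),
        se_c_prime=float(se_cp), se_ab=se_ab,
        p_a=float(p_a), p_b=float(p_b), p_c=float(p_c), p_c_prime=float(p_cp),
        n=n,
    )


def _batched_paths(idx: np.ndarray, x, m, y, C):
    """Path coefficients (a, b, c, c') for each bootstrap index row.

    Solves the three shared-covariate regressions by batched normal
    equations; returns arrays of shape (B,).  Resamples whose mediator
    design is numerically singular get NaN coefficients.
    """
    B, n = idx.shape
    # equilibrate regressor columns (RMS scaling from the full sample) so the
    # singularity check is scale-invariant; coefficients are unscaled after
    sx = float(np.sqrt(np.mean(x**2))) or 1.0
    sm_ = float(np.sqrt(np.mean(m**2))) or 1.0
    sC = np.sqrt(np.mean(C**2, axis=0))
    sC[sC == 0] = 1.0
    ones = np.ones((B, n, 1))
    xs = (x / sx)[idx][..., None]
    ms = (m / sm_)[idx][..., None]
    ys = y[idx]
    Cs = (C / sC)[idx]
    Xm = np.concatenate([ones, xs, Cs], axis=2)
    Xy = np.concatenate([ones, xs, ms, Cs], axis=2)

    def _solve(X, v):
        G = np.einsum("bij,bik->bjk", X, X)
        r = np.einsum("bij,bi->bj", X, v)
        out = np.full((X.shape[0], X.shape[2]), np.nan)
        ok = np.linalg.cond(G) < 1e12
        if ok.any():
            out[ok] = np.linalg.solve(G[ok], r[ok][..., None])[..., 0]
        return out, ok

    beta_m, ok_m = _solve(Xm, ms[..., 0])
    beta_y, ok_y = _solve(Xy, ys)
    beta_t, ok_t = _solve(Xm, ys)
    ok = ok_m & ok_y & ok_t
    a = np.where(ok, beta_m[:, 1], np.nan) * sm_ / sx
    cp = np.where(ok, beta_y[:, 1], np.nan) / sx
    b = np.where(ok, beta_y[:, 2], np.nan) / sm_
    c = np.where(ok, beta_t[:, 1], np.nan) / sx
    return a, b, c, cp, ok


def _sign_p(draws: np.ndarray) -> float:
    """Two-sided bootstrap p for 'effect differs from zero'.

    2 * min(F(0), 1 - F(0)) with the (r+1)/(B+1) continuity adjustment on
    each tail, capped at 1.
    """
    B = len(draws)
    lo = (np.sum(draws <= 0) + 1) / (B + 1)
    hi = (np.sum(draws >= 0) + 1) / (B + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def bootstrap_mediation(
    table: pd.DataFrame,
    design: MediationDesign,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
    ci_method: str = "percentile",
) -> MediationResult:
    """Case-resampling bootstrap of the mediation paths.

    Subjects are resampled with replacement ``n_boot`` times; every path is
    recomputed per resample.  Rank-deficient resamples are redrawn (their
    count is reported; more than 1% triggers a warning).  Reproducible
    given ``seed``.
    """
    if n_boot < 1000:
        raise MediationError("n_boot must be at least 1000")
    if ci_method not in ("percentile", "bc"):
        raise MediationError(f"unknown ci_method {ci_method!r}")
    paths = fit_paths(table, design)
    data = design.resolve(table)
    x, m, y, C, _, _ = _design_matrices(data, design)
    n = len(x)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_bs, b_bs, c_bs, cp_bs, ok = _batched_paths(idx, x, m, y, C)
    n_redraws = 0
    while not ok.all():
        bad = ~ok
        n_redraws += int(bad.sum())
        idx_bad = rng.integers(0, n, size=(int(bad.sum()), n))
        a2, b2, c2, cp2, ok2 = _batched_paths(idx_bad, x, m, y, C)
        a_bs[bad], b_bs[bad], c_bs[bad], cp_bs[bad] = a2, b2, c2, cp2
        ok_new = ok.copy()
        ok_new[bad] = ok2
        ok = ok_new
    if n_redraws > 0.01 * n_boot:
        warnings.warn(
            f"{n_redraws} rank-deficient bootstrap resamples were redrawn "
            f"(> 1% of {n_boot})",
            stacklevel=2,
        )

    ab_bs = a_bs * b_bs
    alpha = 1.0 - ci_level
    if ci_method == "percentile":
        ci = (
            float(np.quantile(ab_bs, alpha / 2)),
            float(np.quantile(ab_bs, 1 - alpha / 2)),
        )
    else:  # bias-corrected
        prop = np.mean(ab_bs < paths.ab)
        prop = min(max(prop, 1 / (n_boot + 1)), n_boot / (n_boot + 1))
        z0 = stats.norm.ppf(prop)
        lo_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(alpha / 2))
        hi_q = stats.norm.cdf(2 * z0 + stats.norm.ppf(1 - alpha / 2))
        ci = (float(np.quantile(ab_bs, lo_q)), float(np.quantile(ab_bs, hi_q)))

    return MediationResult(
        paths=paths,
        ab_boot=ab_bs,
        ci_ab=ci,
        ci_level=ci_level,
        p_ab=_sign_p(ab_bs),
        p_a_boot=_sign_p(a_bs),
        p_b_boot=_sign_p(b_bs),
        p_c_boot=_sign_p(c_bs),
        p_c_prime_boot=_sign_p(cp_bs),
        se_ab_boot=float(np.std(ab_bs, ddof=1)),
        n_boot=n_boot,
        seed=seed,
        ci_method=ci_method,
        n_redraws=n_redraws,
        covariate_names=design.covariates,
    )


NONCAUSAL_SUFFIX = " (statistical pattern; cross-sectional data preclude causal inference)"


def classify_mediation(result: MediationResult, alpha: float = 0.05) -> str:
    """Label the mediation pattern at significance level ``alpha``.

    'full-pattern' = significant indirect effect with a non-significant
    direct effect and a significant total effect; 'partial' = significant
    indirect and direct effects; otherwise 'none'.  The label carries an
    explicit non-causal framing suffix.
    """
    p_ab = result.p_ab
    p_cp = result.p_c_prime_boot
    p_c = result.p_c_boot
    if p_ab < alpha and p_cp >= alpha and p_c < alpha:
        label = "full-pattern"
    elif p_ab < alpha and p_cp < alpha:
        label = "partial"
    else:
        label = "none"
    return label + NONCAUSAL_SUFFIX


def result_to_dict(result: MediationResult) -> dict:
    """JSON-serialisable summary (bootstrap draws are not included)."""
    p = result.paths
    return {
        "a": p.a, "b": p.b, "c": p.c, "c_prime": p.c_prime, "ab": p.ab,
        "se_a": p.se_a, "se_b": p.se_b, "se_c": p.se_c,
        "se_c_prime": p.se_c_prime, "se_ab": p.se_ab,
        "se_ab_boot": result.se_ab_boot,
        "p_a": p.p_a, "p_b": p.p_b, "p_c": p.p_c, "p_c_prime": p.p_c_prime,
        "p_ab": result.p_ab,
        "p_a_boot": result.p_a_boot, "p_b_boot": result.p_b_boot,
        "p_c_boot": result.p_c_boot, "p_c_prime_boot": result.p_c_prime_boot,
        "ci_ab": list(result.ci_ab), "ci_level": result.ci_level,
        "ci_method": result.ci_method,
        "n": p.n, "n_boot": result.n_boot, "seed": result.seed,
        "n_redraws": result.n_redraws,
        "covariates": list(result.covariate_names),
    }
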