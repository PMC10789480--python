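"""Cognitive composites, polynomial-age regressions, robust refits, mediation.

The inferential chain is: (1) reduce cognitive sub-test batteries to first
principal components; (2) regress outcomes on a degree-2 age polynomial,
effect-coded sex and their interactions, reporting standardized
coefficients, t, p, R-squared and partial eta-squared; (3) refit with
Huber-loss robust regression to check outlier sensitivity; (4) test
three-variable mediation (exposure -> mediator -> outcome, covariates in
every equation) by the product of coefficients, with a first-order Sobel
standard error and a seeded percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)

HUBER_TUNING = 1.345


def _zscore(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("zero-variance variable cannot be standardized")
    return (x - x.mean()) / sd


def pc1_composite(scores: np.ndarray, column_names: list[str] | None = None) -> np.ndarray:
    """First principal component of column-standardized scores.

    Rescaled to unit SD, sign fixed so the composite correlates positively
    with the across-column row mean.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] <= x.shape[1]:
        raise ValidationError("need an (n x k) matrix with n > k >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores contain missing/non-finite entries")
    names = column_names or [f"col{i}" for i in range(x.shape[1])]
    sd = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(f"zero-variance column(s): {[names[i] for i in dead]}")
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pc = u[:, 0] * s[0]
    if np.corrcoef(pc, z.mean(axis=1))[0, 1] < 0:
        pc = -pc
    return pc / pc.std(ddof=1)


@dataclass
class RegressionResult:
    """Term-wise summary of one least-squares (or robust) fit."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    r_squared: float
    partial_eta2: dict[str, float]
    n: int
    converged: bool = True
    design: np.ndarray = field(repr=False, default=None)
    outcome: np.ndarray = field(repr=False, default=None)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        i = self.terms.index(term)
        half = sps.t.ppf(0.5 + level / 2.0, self.df_resid) * self.se[i]
        return float(self.beta[i] - half), float(self.beta[i] + half)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
                "partial_eta2": [self.partial_eta2.get(t_, np.nan) for t_ in self.terms],
            }
        )


def _ols(y: np.ndarray, x: np.ndarray, terms: list[str]) -> RegressionResult:
    n, k = x.shape
    if n <= k + 1:
        raise InsufficientDataError(f"{n} cases for {k} design columns")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        aliased = []
        for j in range(k):
            others = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(x):
                aliased.append(terms[j])
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - k
    sse = float(resid @ resid)
    sigma2 = sse / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    eta = {}
    for j, name in enumerate(terms):
        if name == "intercept":
            continue
        eta[name] = float(t[j] ** 2 / (t[j] ** 2 + df))
    return RegressionResult(
        terms=terms,
        beta=beta,
        se=se,
        t=t,
        p=p,
        df_resid=df,
        r_squared=r2,
        partial_eta2=eta,
        n=n,
        design=x,
        outcome=y,
    )


def age_polynomial(
    age: np.ndarray,
    mode: str = "orthogonal",
    moments: tuple[float, float] | None = None,
) -> np.ndarray:
    """Degree-2 age basis as an (n x 2) matrix of unit-SD columns.

    ``"orthogonal"``: sample-orthogonalized polynomial (QR of the centered
    Vandermonde), each column scaled to SD 1 -- invariant to shifting and
    scaling raw age.  ``"standardized"``: the z-scored age and its centered,
    variance-standardized square.  When ``moments`` (mean, SD) are supplied
    in standardized mode they replace the sample moments, and the quadratic
    column becomes (z^2 - 1)/sqrt(0.8) -- the population basis of a uniform
    age distribution, matching the synthetic cohort's planted coefficients.
    """
    age = np.asarray(age, dtype=float)
    if mode == "orthogonal":
        v = np.column_stack([np.ones_like(age), age, age**2])
        q, _ = np.linalg.qr(v)
        cols = q[:, 1:3]
        cols = cols / cols.std(axis=0, ddof=1)
        for j in range(2):
            ref = age if j == 0 else (age - age.mean()) ** 2
            if np.corrcoef(cols[:, j], ref)[0, 1] < 0:
                cols[:, j] = -cols[:, j]
        return cols
    if mode == "standardized":
        if moments is not None:
            mu, sd = moments
            z = (age - mu) / sd
            q = (z**2 - 1.0) / np.sqrt(0.8)
        else:
            z = _zscore(age)
            q = z**2
            q = (q - q.mean()) / q.std(ddof=1)
        return np.column_stack([z, q])
    raise ValidationError(f"unknown polynomial mode: {mode!r}")


def encode_sex(sex: np.ndarray) -> np.ndarray:
    """Effect coding: female +0.5, male -0.5 (accepts F/M strings or 0/1)."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "UOS":
        up = np.char.upper(arr.astype(str))
        return np.where(np.isin(up, ("F", "FEMALE")), 0.5, -0.5)
    return np.where(arr.astype(float) > 0.5, 0.5, -0.5)


def fit_age_model(
    outcome: np.ndarray,
    table: pd.DataFrame,
    *,
    covariates: tuple[str, ...] = (),
    covariate_interactions: bool = False,
    poly: str = "orthogonal",
    age_moments: tuple[float, float] | None = None,
    standardize: bool = True,
    age_col: str = "age",
    sex_col: str = "sex",
) -> RegressionResult:
    """Least-squares fit of outcome ~ poly(age, 2) * sex [+ covariates].

    Base terms: age^1, age^2, sex, age^1:sex, age^2:sex.  Each covariate
    adds a main-effect column; with ``covariate_interactions`` its two- and
    three-way interactions with age and sex are added too (the structure
    used when asking whether a brain measure predicts cognition beyond
    age).  With ``standardize`` the outcome and continuous predictors are
    z-scored so coefficients are standardized betas.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(table):
        raise ValidationError("outcome length must match table rows")
    mask = np.isfinite(y) & np.isfinite(table[age_col].to_numpy(dtype=float))
    for c in covariates:
        mask &= np.isfinite(table[c].to_numpy(dtype=float))
    y = y[mask]
    sub = table.loc[mask]
    if standardize:
        y = _zscore(y)
    ages = age_polynomial(sub[age_col].to_numpy(dtype=float), mode=poly, moments=age_moments)
    sex = encode_sex(sub[sex_col].to_numpy())
    cols = [np.ones_like(y), ages[:, 0], ages[:, 1], sex, ages[:, 0] * sex, ages[:, 1] * sex]
    terms = ["intercept", "age1", "age2", "sex", "age1:sex", "age2:sex"]
    for c in covariates:
        v = sub[c].to_numpy(dtype=float)
        if standardize:
            v = _zscore(v)
        cols.append(v)
        terms.append(c)
        if covariate_interactions:
            for extra, name in (
                (ages[:, 0], f"{c}:age1"),
                (ages[:, 1], f"{c}:age2"),
                (sex, f"{c}:sex"),
                (ages[:, 0] * sex, f"{c}:age1:sex"),
                (ages[:, 1] * sex, f"{c}:age2:sex"),
            ):
                cols.append(v * extra)
                terms.append(name)
    return _ols(y, np.column_stack(cols), terms)


def partial_eta_squared(result: RegressionResult, term: str) -> float:
    """Partial eta-squared for one term via a type-III-style term drop.

    Refits without the term's column(s); eta_p^2 = (SSE_reduced - SSE_full)
    / SSE_reduced = SS_term / (SS_term + SS_residual).  For a 1-df term this
    equals t^2 / (t^2 + df).
    """
    if term not in result.terms:
        raise KeyError(f"term {term!r} not in model: {result.terms}")
    if result.design is None:
        return result.partial_eta2[term]
    idx = [j for j, t_ in enumerate(result.terms) if t_ == term]
    x_red = np.delete(result.design, idx, axis=1)
    y = result.outcome
    beta_full, *_ = np.linalg.lstsq(result.design, y, rcond=None)
    sse_full = float(np.sum((y - result.design @ beta_full) ** 2))
    beta_red, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    sse_red = float(np.sum((y - x_red @ beta_red) ** 2))
    if sse_red == 0:
        return 0.0
    return max(0.0, (sse_red - sse_full) / sse_red)


def robust_fit(
    outcome: np.ndarray,
    design: np.ndarray,
    terms: list[str] | None = None,
    *,
    tuning: float = HUBER_TUNING,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> RegressionResult:
    """Huber-loss regression by iteratively reweighted least squares.

    Residuals are standardized by the normalized median absolute deviation
    each iteration; weights are ``min(1, tuning / |r_std|)``.  Converges
    when the largest coefficient change drops below ``tol``; otherwise the
    result carries ``converged=False``.  As ``tuning -> inf`` this is
    ordinary least squares.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    terms = terms or [f"x{j}" for j in range(x.shape[1])]
    n, k = x.shape
    if n <= k + 1:
        raise InsufficientDataError(f"{n} cases for {k} design columns")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        resid = y - x @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6744897501960817
        if scale <= 0:
            converged = True
            break
        u = np.abs(resid / scale)
        w = np.where(u <= tuning, 1.0, tuning / np.maximum(u, 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    resid = y - x @ beta
    df = n - k
    # Weighted-LS covariance at the final weights; approximate for inference.
    xtwx_inv = np.linalg.inv((x * w[:, None]).T @ x)
    sigma2 = float(resid @ (w * resid)) / df
    se = np.sqrt(np.diag(xtwx_inv) * sigma2)
    t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - float(resid @ (w * resid)) / tss if tss > 0 else 0.0
    eta = {
        name: float(t[j] ** 2 / (t[j] ** 2 + df))
        for j, name in enumerate(terms)
        if name != "intercept"
    }
    return RegressionResult(
        terms=list(terms),
        beta=beta,
        se=se,
        t=t,
        p=p,
        df_resid=df,
        r_squared=r2,
        partial_eta2=eta,
        n=n,
        converged=converged,
        design=x,
        outcome=y,
    )


@dataclass
class MediationResult:
    """Product-of-coefficients mediation summary.

    a: exposure -> mediator; b: mediator -> outcome given exposure;
    c: total exposure -> outcome; c_prime: direct effect.  The indirect
    effect is a*b; percent mediated is 100 * a*b / c (undefined when |c| is
    below tolerance).  sobel_z uses the first-order delta-method SE; the
    bootstrap CI is a seeded percentile interval over cases.
    """

    a: float
    b: float
    c: float
    c_prime: float
    se_a: float
    se_b: float
    indirect: float
    percent_mediated: float | None
    sobel_z: float
    sobel_p: float
    ci_level: float
    ci_low: float | None
    ci_high: float | None
    reps: int
    seed: int | None
    n: int


def _simple_ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(np.linalg.inv(x.T @ x)) * sigma2)
    return beta, se, df


def _paths(y: np.ndarray, m: np.ndarray, x: np.ndarray, cov: np.ndarray):
    ones = np.ones((len(y), 1))
    dm = np.column_stack([ones, x, cov]) if cov.size else np.column_stack([ones, x])
    beta_m, se_m, _ = _simple_ols(m, dm)
    dy = (
        np.column_stack([ones, x, m, cov])
        if cov.size
        else np.column_stack([ones, x, m])
    )
    beta_y, se_y, _ = _simple_ols(y, dy)
    beta_t, _, _ = _simple_ols(y, dm)
    a, se_a = beta_m[1], se_m[1]
    c_prime = beta_y[1]
    b, se_b = beta_y[2], se_y[2]
    c = beta_t[1]
    return a, se_a, b, se_b, c, c_prime


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    reps: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Covariate-adjusted three-variable mediation.

    x, m, y are z-scored; covariates (n x q) enter every equation.  Three
    regressions give the paths: m ~ x + cov (a), y ~ x + m + cov (b, c'),
    y ~ x + cov (c).  For complete-case linear fits c = c' + a*b exactly.
    """
    x = _zscore(np.asarray(x, dtype=float))
    m = _zscore(np.asarray(m, dtype=float))
    y = _zscore(np.asarray(y, dtype=float))
    n = len(y)
    if len(x) != n or len(m) != n:
        raise ValidationError("x, m, y must have equal length")
    cov = (
        np.asarray(covariates, dtype=float).reshape(n, -1)
        if covariates is not None
        else np.empty((n, 0))
    )
    if n < 10 + cov.shape[1]:
        raise InsufficientDataError(f"need >= {10 + cov.shape[1]} complete cases, got {n}")
    a, se_a, b, se_b, c, c_prime = _paths(y, m, x, cov)
    indirect = a * b
    sobel_se = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    sobel_z = indirect / sobel_se if sobel_se > 0 else 0.0
    sobel_p = 2.0 * sps.norm.sf(abs(sobel_z))
    percent = 100.0 * indirect / c if abs(c) >= 1e-10 else None

    ci_low = ci_high = None
    if reps > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(reps)
        for r in range(reps):
            idx = rng.integers(0, n, size=n)
            try:
                ab_a, _, ab_b, _, _, _ = _paths(y[idx], m[idx], x[idx], cov[idx])
                boots[r] = ab_a * ab_b
            except np.linalg.LinAlgError:
                boots[r] = np.nan
        boots = boots[np.isfinite(boots)]
        alpha = 1.0 - ci_level
        ci_low, ci_high = (
            float(np.quantile(boots, alpha / 2.0)),
            float(np.quantile(boots, 1.0 - alpha / 2.0)),
        )
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        c_prime=float(c_prime),
        se_a=float(se_a),
        se_b=float(se_b),
        indirect=float(indirect),
        percent_mediated=percent,
        sobel_z=float(sobel_z),
        sobel_p=float(sobel_p),
        ci_level=ci_level,
        ci_low=ci_low,
        ci_high=ci_high,
        reps=reps,
        seed=seed,
        n=n,
    )
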