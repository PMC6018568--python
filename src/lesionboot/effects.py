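"""Partial-correlation effect sizes and closed-form inference helpers.

This module is the statistical core of the package: the signed partial
correlation between a lesion-load vector and a behavioural score after
linearly removing a set of covariates, its squared value (the proportion of
variance explained uniquely by lesion load), the flat-prior credible
interval for that R-squared, and closed-form calculators for the smallest
R-squared that reaches significance at a given sample size, the analytic
power of the partial-correlation test, and the probability that a small
sample inverts the sign of the effect.

Conventions used throughout:

* ``k`` is the number of covariates partialled out (five in the standard
  lesion-deficit design: four nuisance behavioural scores plus lesion size).
* The t statistic for a partial correlation ``r`` has ``df = n - 2 - k``
  degrees of freedom and equals ``r * sqrt(df / (1 - r**2))``.
* Interval and power computations use the Fisher-z transform of the partial
  correlation, whose posterior / sampling standard error is
  ``1 / sqrt(n - k - 3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PartialCorrResult",
    "CredibleInterval",
    "partial_correlation",
    "critical_r2",
    "analytic_power",
    "credible_interval_r2",
    "sign_error_probability",
]


@dataclass(frozen=True)
class PartialCorrResult:
    """Partial correlation between two variables given covariates.

    Attributes
    ----------
    r_partial : float
        Signed partial correlation.
    r2 : float
        Squared partial correlation — the proportion of variance in the
        target explained uniquely by the predictor.
    t_stat : float
        t statistic, ``r * sqrt(df / (1 - r^2))``.
    df : int
        Residual degrees of freedom, ``n - 2 - k``.
    p_two_sided : float
        Two-sided p value from the t distribution.
    n : int
        Sample size.
    k : int
        Number of covariates partialled out.
    """

    r_partial: float
    r2: float
    t_stat: float
    df: int
    p_two_sided: float
    n: int
    k: int


@dataclass(frozen=True)
class CredibleInterval:
    """Equal-tailed credible interval for a squared partial correlation."""

    lower_r2: float
    upper_r2: float
    level: float
    method: str = "flat-prior-fisher-z"

    def contains(self, r2) -> np.ndarray:
        """Elementwise test for ``lower_r2 <= r2 <= upper_r2``."""
        r2 = np.asarray(r2)
        return (r2 >= self.lower_r2) & (r2 <= self.upper_r2)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residual of ``v`` after OLS on the columns of ``z``."""
    coef, *_ = np.linalg.lstsq(z, v, rcond=None)
    return v - z @ coef


def partial_correlation(y, x, covariates) -> PartialCorrResult:
    """Partial correlation of ``y`` and ``x`` given ``covariates``.

    Both ``y`` and ``x`` are regressed (with an intercept) on the covariate
    matrix; the correlation of the two residual vectors is the partial
    correlation. The t test uses ``df = n - 2 - k``.

    Parameters
    ----------
    y : (n,) array_like
        Target variable (e.g. nonword-repetition T-scores).
    x : (n,) array_like
        Predictor of interest (e.g. lesion load in the ROI).
    covariates : (n, k) array_like
        Covariates to partial out of both variables.

    Raises
    ------
    ValueError
        If inputs contain missing values, ``n <= k + 2``, or either
        residual vector is (numerically) constant.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.size:
        c = c.T
    n = y.size
    k = c.shape[1]
    if x.size != n or c.shape[0] != n:
        raise ValueError("y, x and covariates must have matching lengths")
    if not (np.isfinite(y).all() and np.isfinite(x).all() and np.isfinite(c).all()):
        raise ValueError("missing or non-finite values are not allowed")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (got n={n}, k={k})")

    z = np.column_stack([np.ones(n), c])
    ry = _residualize(y, z)
    rx = _residualize(x, z)
    sy = float(np.sqrt(ry @ ry))
    sx = float(np.sqrt(rx @ rx))
    scale = max(float(np.abs(y).max()), 1.0) * n
    if sy <= 1e-12 * scale or sx <= 1e-12 * max(float(np.abs(x).max()), 1.0) * n:
        raise ValueError("degenerate sample: constant residual vector")

    r = float(np.clip((ry @ rx) / (sy * sx), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return PartialCorrResult(
        r_partial=r, r2=r * r, t_stat=float(t), df=df,
        p_two_sided=float(p), n=n, k=k,
    )


def critical_r2(n: int, k: int, alpha: float, tails: int = 2) -> float:
    """Smallest squared partial correlation declared significant.

    Returns ``t_crit**2 / (t_crit**2 + df)`` with ``df = n - 2 - k`` and
    ``t_crit`` the ``alpha``-level (two-sided by default) t quantile. This
    is the significance "floor": any resample whose R-squared falls below it
    cannot reach ``p < alpha``.
    """
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"invalid degrees of freedom df={df} (n={n}, k={k})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    return float(t_crit**2 / (t_crit**2 + df))


def analytic_power(rho2: float, n: int, k: int, alpha: float) -> float:
    """Power of the two-sided partial-correlation test, Fisher-z approximation.

    With population squared partial correlation ``rho2``, the Fisher-z
    estimate is approximately Normal(atanh(sqrt(rho2)), 1/(n-k-3)), so

        power = Phi(zbar/SE - z_{1-alpha/2}) + Phi(-zbar/SE - z_{1-alpha/2})

    At ``rho2 = 0`` this reduces to ``alpha`` (the size of the test).
    """
    if not 0 <= rho2 < 1:
        raise ValueError("rho2 must be in [0, 1)")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (got n={n}, k={k})")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    zbar = np.arctanh(np.sqrt(rho2))
    se = 1.0 / np.sqrt(n - k - 3)
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(zbar / se - zc) + stats.norm.cdf(-zbar / se - zc))


def credible_interval_r2(
    r2: float, n: int, k: int, level: float = 0.95, sign: int = 1
) -> CredibleInterval:
    """Flat-prior credible interval for a squared partial correlation.

    Under a flat prior on the Fisher-z scale the posterior of z given the
    observed partial correlation is Normal(atanh(r_obs), 1/(n-k-3)). The
    equal-tailed interval on z is mapped back through tanh to the r scale
    and squared. If the r interval straddles zero the R-squared interval is
    [0, max(bound^2)] — R-squared cannot resolve the sign.

    Parameters
    ----------
    r2 : float
        Observed squared partial correlation.
    n, k : int
        Sample size and number of covariates.
    level : float
        Credible level (default 0.95).
    sign : {-1, +1}
        Sign of the observed partial correlation; irrelevant to the
        R-squared interval (the construction is sign-symmetric) but kept so
        callers can be explicit about direction.
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n - k - 3 <= 0:
        raise ValueError(f"need n > k + 3 (got n={n}, k={k})")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    z_obs = np.arctanh(np.sqrt(r2)) * sign
    se = 1.0 / np.sqrt(n - k - 3)
    zq = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    r_lo = np.tanh(z_obs - zq * se)
    r_hi = np.tanh(z_obs + zq * se)
    if r_lo < 0 < r_hi:
        lower, upper = 0.0, float(max(r_lo**2, r_hi**2))
    else:
        lower, upper = float(min(r_lo**2, r_hi**2)), float(max(r_lo**2, r_hi**2))
    return CredibleInterval(lower_r2=lower, upper_r2=upper, level=level)


def sign_error_probability(rho2: float, n: int, k: int) -> float:
    """Probability the estimated partial correlation has the wrong sign.

    On the Fisher-z scale the estimate is Normal(atanh(sqrt(rho2)),
    1/(n-k-3)); the wrong-sign probability is the mass on the other side of
    zero, ``Phi(-atanh(sqrt(rho2)) * sqrt(n-k-3))``.
    """
    if not 0 <= rho2 < 1:
        raise ValueError("rho2 must be in [0, 1)")
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 (got n={n}, k={k})")
    if rho2 == 0:
        warnings.warn("rho2 = 0: effect direction undefined; returning 0.5")
        return 0.5
    return float(stats.norm.cdf(-np.arctanh(np.sqrt(rho2)) * np.sqrt(n - k - 3)))
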