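"""Synthetic lesion-deficit cohorts with a calibrated target effect size.

The generator draws (latent ROI lesion load, four nuisance behavioural
scores, log lesion size) from a joint Gaussian, transforms them to their
observed scales (clipped T-scores, clipped lognormal lesion size, lesion
load clipped to a fraction), and builds the target score as a linear
function of lesion load and the nuisance scores plus Gaussian noise. The
effect coefficient is solved in closed form from the observed-variable
correlation matrix (estimated once by a large fixed-seed Monte-Carlo draw)
so that the population squared partial correlation between ROI lesion load
and the target score, given the four nuisance scores and lesion size,
equals the configured target.

Because a study bootstrap resamples one *fixed* cohort, the module also
provides an exact in-sample adjustment (`fix_sample_partial_r2`) that
rotates the lesion-load vector in the residual space of the covariates so
the sample partial R-squared equals a requested value to machine precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COVARIATE_COLUMNS, SCORE_COLUMNS, CalibratedEffect, GeneratorConfig

__all__ = [
    "calibrate_generator",
    "generate_cohort",
    "fix_sample_partial_r2",
    "read_cohort",
    "write_cohort",
]

_CALIBRATION_SEED = 20230719  # fixed: calibration is a deterministic function of config
_CALIBRATION_DRAWS = 400_000


def _observed_from_latent(latent: np.ndarray, config: GeneratorConfig):
    """Map latent N(0,1) draws to observed (load, 4 scores, lesion size).

    ``latent`` has columns (load, wpn, sema, recm, awp, log-size), already
    correlated. Returns (load, nuisance_scores (n,4), size_cm3).
    """
    lo, hi = config.load_clip
    load = np.clip(config.load_mean + config.load_sd * latent[:, 0], lo, hi)
    scores = np.clip(
        config.score_mean + config.score_sd * latent[:, 1:5],
        config.score_clip[0], config.score_clip[1],
    )
    mu, sigma = config.lesion_size_lognormal_params
    size = np.clip(np.exp(mu + sigma * latent[:, 5]),
                   config.lesion_size_range[0], config.lesion_size_range[1])
    return load, scores, size


def _draw_latent(n: int, config: GeneratorConfig, rng: np.random.Generator):
    chol = np.linalg.cholesky(
        config.joint_latent_corr() + 1e-12 * np.eye(6)
    )
    return rng.standard_normal((n, 6)) @ chol.T


def calibrate_generator(
    target_partial_r2: float | None = None, config: GeneratorConfig | None = None
) -> GeneratorConfig:
    """Solve the effect coefficients for a target population partial R².

    The squared partial correlation between load L and target score y given
    covariates C satisfies  r² = beta² v / (beta² v + s²)  where v is the
    residual variance of (standardised) L given C and s² the noise
    variance. Requiring Var(y*) = 1 for the standardised target yields a
    quadratic in beta solved here from Monte-Carlo estimates of the
    observed-variable correlation matrix (fixed internal seed, so the
    calibration is a deterministic function of the configuration).

    Returns a copy of ``config`` with ``config.calibration`` set.
    """
    if config is None:
        config = GeneratorConfig()
    if target_partial_r2 is None:
        target_partial_r2 = config.target_partial_r2
    if not 0 <= target_partial_r2 < 1:
        raise ValueError("target_partial_r2 must be in [0, 1)")
    config = config.replace(target_partial_r2=float(target_partial_r2))

    rng = np.random.default_rng(_CALIBRATION_SEED)
    latent = _draw_latent(_CALIBRATION_DRAWS, config, rng)
    load, scores, size = _observed_from_latent(latent, config)

    l_mean, l_sd = float(load.mean()), float(load.std())
    # standardised observed variables: load, then the 5 covariates
    z = np.column_stack([
        (load - l_mean) / l_sd,
        (scores - config.score_mean) / config.score_sd,
        (size - size.mean()) / size.std(),
    ])
    corr = np.corrcoef(z, rowvar=False)
    rho_lc = corr[0, 1:]
    r_cc = corr[1:, 1:]
    resid_var = float(1.0 - rho_lc @ np.linalg.solve(r_cc, rho_lc))

    gamma = config.nuisance_weight
    g = np.array([gamma] * 4 + [0.0])  # direct covariate weights on y*
    t = config.target_partial_r2
    if t == 0.0:
        beta = 0.0
        noise_var = 1.0 - float(g @ r_cc @ g)
    else:
        a = 1.0 + resid_var * (1.0 - t) / t
        b = 2.0 * float(g @ rho_lc)
        c = float(g @ r_cc @ g)
        if c >= 1.0:
            raise ValueError("nuisance_weight explains the full target variance")
        disc = b * b - 4.0 * a * (c - 1.0)
        beta = (-b + config.effect_sign * np.sqrt(disc)) / (2.0 * a)
        noise_var = beta * beta * resid_var * (1.0 - t) / t
    if noise_var <= 0:
        raise ValueError("calibration produced non-positive noise variance")

    calib = CalibratedEffect(
        beta=float(beta), gamma=float(gamma), noise_sd=float(np.sqrt(noise_var)),
        load_mc_mean=l_mean, load_mc_sd=l_sd, load_resid_var=resid_var,
        target_partial_r2=float(t),
    )
    return config.replace(calibration=calib)


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a cohort table plus the latent per-patient true-ROI lesion load.

    Returns ``(cohort, lesion_load)`` where ``cohort`` has columns
    ``patient_id, score_repn, score_wpn, score_sema, score_recm, score_awp,
    lesion_size_cm3`` and ``lesion_load`` is the fraction of the true ROI
    that is abnormal for each patient (the predictor the effect was
    calibrated on).
    """
    if config.calibration is None:
        raise ValueError("config must be calibrated first (calibrate_generator)")
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    n = config.n_patients
    rng = np.random.default_rng(seed)
    cal = config.calibration

    latent = _draw_latent(n, config, rng)
    load, scores, size = _observed_from_latent(latent, config)
    l_std = (load - cal.load_mc_mean) / cal.load_mc_sd
    s_std = (scores - config.score_mean) / config.score_sd
    y_star = (
        cal.beta * l_std
        + cal.gamma * s_std.sum(axis=1)
        + cal.noise_sd * rng.standard_normal(n)
    )
    y = np.clip(config.score_mean + config.score_sd * y_star,
                config.score_clip[0], config.score_clip[1])

    cohort = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        SCORE_COLUMNS[0]: y,
        SCORE_COLUMNS[1]: scores[:, 0],
        SCORE_COLUMNS[2]: scores[:, 1],
        SCORE_COLUMNS[3]: scores[:, 2],
        SCORE_COLUMNS[4]: scores[:, 3],
        "lesion_size_cm3": size,
    })
    return cohort, load


def _covariate_matrix(cohort: pd.DataFrame) -> np.ndarray:
    return cohort.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)


def fix_sample_partial_r2(
    cohort: pd.DataFrame,
    lesion_load: np.ndarray,
    exact_r2: float,
    sign: int = -1,
) -> np.ndarray:
    """Adjust lesion load so the *in-sample* partial R² is exact.

    Decomposes the covariate-residualised lesion load into its component
    along the residualised target score and the orthogonal remainder, then
    rescales the two components so the sample partial correlation equals
    ``sign * sqrt(exact_r2)`` to machine precision. The total residual
    magnitude is preserved; if the adjusted values leave [0, 1] they are
    re-mapped affinely (which cannot change the partial correlation).

    Passing the current sample value (with its sign) returns the input
    unchanged up to floating-point round-off.
    """
    if not 0 <= exact_r2 < 1:
        raise ValueError("exact_r2 must be in [0, 1)")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    x = np.asarray(lesion_load, dtype=float).copy()
    y = cohort[SCORE_COLUMNS[0]].to_numpy(dtype=float)
    c = _covariate_matrix(cohort)
    n, k = c.shape
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 rows (got n={n}, k={k})")

    z = np.column_stack([np.ones(n), c])
    q, _ = np.linalg.qr(z)
    ry = y - q @ (q.T @ y)
    rx = x - q @ (q.T @ x)
    norm_y = np.linalg.norm(ry)
    norm_x = np.linalg.norm(rx)
    if norm_y < 1e-12 or norm_x < 1e-12:
        raise ValueError("degenerate sample: constant residual vector")

    e_y = ry / norm_y
    along = float(rx @ e_y)
    perp = rx - along * e_y
    norm_perp = np.linalg.norm(perp)
    if norm_perp < 1e-12 * norm_x:
        raise ValueError(
            "lesion load residual is collinear with the target residual; "
            "cannot rotate to the requested partial correlation"
        )
    e_perp = perp / norm_perp

    r_target = sign * np.sqrt(exact_r2)
    new_resid = norm_x * (r_target * e_y + np.sqrt(1.0 - r_target**2) * e_perp)
    adjusted = (x - rx) + new_resid

    if adjusted.min() < 0.0 or adjusted.max() > 1.0:
        lo, hi = adjusted.min(), adjusted.max()
        adjusted = 0.005 + 0.99 * (adjusted - lo) / (hi - lo)
    return adjusted


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the standard column header."""
    cols = ["patient_id", *SCORE_COLUMNS, "lesion_size_cm3"]
    cohort.loc[:, cols].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema and basic invariants."""
    df = pd.read_csv(Path(path))
    expected = ["patient_id", *SCORE_COLUMNS, "lesion_size_cm3"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    numeric = df[expected[1:]]
    if numeric.isna().any().any():
        raise ValueError("cohort contains missing values")
    if (df["lesion_size_cm3"] <= 0).any():
        raise ValueError("lesion_size_cm3 must be positive")
    return df[expected]
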