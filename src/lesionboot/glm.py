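"""Voxelwise mass-univariate regression and FWE-corrected ROI extraction.

Each in-mask voxel's fuzzy abnormality is regressed on seven columns
(intercept, five behavioural T-scores, lesion size) by ordinary least
squares; the statistic of interest is the t value of the nonword-repetition
coefficient. Family-wise error across voxels is controlled either by a
Freedman-Lane max-|t| permutation scheme or by Bonferroni; the ROI is the
set of suprathreshold voxels whose coefficient has the hypothesised
(negative) direction — greater abnormality with poorer scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import SCORE_COLUMNS
from .lesion_io import AnalysisMask, stack_values

__all__ = [
    "DesignMatrix",
    "VoxelStatMap",
    "RoiMask",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "fwe_threshold",
    "extract_lesion_load",
]

T_SENTINEL = 1e6  # |t| cap for zero-residual-variance voxels with signal

DESIGN_COLUMNS = ("intercept",) + SCORE_COLUMNS + ("lesion_size_cm3",)
TARGET_COLUMN = SCORE_COLUMNS[0]  # nonword repetition


@dataclass
class DesignMatrix:
    """n x 7 design: intercept + five behavioural scores + lesion size."""

    values: np.ndarray
    column_names: tuple = DESIGN_COLUMNS

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def target_index(self) -> int:
        return self.column_names.index(TARGET_COLUMN)

    def reduced(self) -> np.ndarray:
        """Design with the regressor of interest removed (nuisance-only)."""
        keep = [j for j in range(self.values.shape[1]) if j != self.target_index]
        return self.values[:, keep]


@dataclass
class VoxelStatMap:
    """Per-voxel t statistics for the regressor of interest."""

    t_values: np.ndarray  # one value per in-mask voxel
    df: int
    contrast: str
    mask: AnalysisMask
    n_capped: int = 0

    def volume(self) -> np.ndarray:
        out = np.zeros(self.mask.in_mask.shape)
        out[self.mask.in_mask] = self.t_values
        return out


@dataclass
class RoiMask:
    """FWE-surviving voxels with the hypothesised effect direction."""

    voxels: np.ndarray  # (m, 3) voxel indices
    threshold_used: float
    method: str
    grid_shape: tuple
    alpha: float
    n_voxels: int = field(init=False)

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            self.voxels = self.voxels.reshape(0, 3)
        self.n_voxels = self.voxels.shape[0]

    def as_volume(self) -> np.ndarray:
        out = np.zeros(self.grid_shape, dtype=np.uint8)
        if self.n_voxels:
            out[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = 1
        return out


def build_design_matrix(cohort) -> DesignMatrix:
    """Design matrix [intercept, repn, wpn, sema, recm, awp, lesion_size]."""
    cols = [c for c in DESIGN_COLUMNS if c != "intercept"]
    x = cohort.loc[:, cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("cohort rows contain missing values")
    design = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(
                design[:, :j]
            ):
                collinear.append(DESIGN_COLUMNS[j])
        raise ValueError(f"design matrix is rank deficient; collinear: {collinear}")
    return DesignMatrix(values=design)


def _masked_data(fuzzies, mask: AnalysisMask) -> np.ndarray:
    data = stack_values(fuzzies)
    if data.shape[1:] != mask.in_mask.shape:
        raise ValueError("fuzzy volumes and mask are on different grids")
    return data[:, mask.in_mask]


def _glm_t(y: np.ndarray, x: np.ndarray, target_idx: int):
    """t statistics for one coefficient, shared design across voxel columns."""
    n, p = x.shape
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    var_b = sigma2 * xtx_inv[target_idx, target_idx]
    se = np.sqrt(var_b)
    coef = beta[target_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    degenerate = se <= 1e-12 * max(np.abs(y).max(), 1.0)
    n_capped = 0
    if degenerate.any():
        noisy = degenerate & (np.abs(coef) > 1e-12)
        t[noisy] = np.sign(coef[noisy]) * T_SENTINEL
        t[degenerate & ~noisy] = 0.0
        n_capped = int(noisy.sum())
    t = np.clip(t, -T_SENTINEL, T_SENTINEL)
    return t, df, n_capped


def fit_voxelwise_glm(fuzzies, design: DesignMatrix, mask: AnalysisMask) -> VoxelStatMap:
    """OLS of fuzzy abnormality on the design at every in-mask voxel.

    The t map is for the nonword-repetition coefficient. Voxels with zero
    residual variance get t = 0 (pure-nuisance fit) or a large-magnitude
    sentinel (perfect signal fit); both are counted and logged.
    """
    if design.n < 10:
        raise ValueError("need at least 10 patients for the voxelwise GLM")
    if mask.n_voxels == 0:
        raise ValueError("analysis mask is empty")
    y = _masked_data(fuzzies, mask)
    if y.shape[0] != design.n:
        raise ValueError("number of volumes does not match the design matrix")
    t, df, n_capped = _glm_t(y, design.values, design.target_index)
    if n_capped:
        warnings.warn(f"{n_capped} voxels had zero residual variance; t capped")
    return VoxelStatMap(t_values=t, df=df, contrast=f"{TARGET_COLUMN} (negative)",
                        mask=mask, n_capped=n_capped)


def _freedman_lane_max_null(y, design: DesignMatrix, n_perm, rng, tails):
    """Null distribution of the max voxelwise statistic under permutation.

    Freedman-Lane: residualise the data on the reduced (nuisance-only)
    design, permute those residuals, add back the nuisance fit, and refit
    the full model. The max over voxels of the chosen statistic (|t| for
    two tails, -t for the negative tail) is recorded per permutation.

    Because the nuisance fit is orthogonal to the residualised regressor of
    interest, the permuted-model t statistics reduce to closed expressions
    in the permuted reduced-model residuals, so each permutation costs one
    (k+2) x n by n x V matrix product instead of a full refit.
    """
    x = design.values
    z = design.reduced()
    qz, _ = np.linalg.qr(z)
    e = y - qz @ (qz.T @ y)  # reduced-model residuals, n x V
    xt = x[:, design.target_index]
    xt_res = xt - qz @ (qz.T @ xt)  # regressor of interest, nuisance-removed
    sxx = float(xt_res @ xt_res)
    n, df = y.shape[0], y.shape[0] - x.shape[1]
    e_ss = np.einsum("ij,ij->j", e, e)  # invariant under row permutation
    # stack [x_res'; Qz'] so one GEMM per permutation yields both the
    # numerator and the permuted reduced-model RSS
    m = np.vstack([xt_res, qz.T])
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        inv = np.argsort(rng.permutation(n))
        g = m[:, inv] @ e
        a = g[0]  # x_res' P e
        rss_z = e_ss - np.einsum("ij,ij->j", g[1:], g[1:])
        rss_full = np.maximum(rss_z - a * a / sxx, 1e-300)
        with np.errstate(divide="ignore"):
            t_star = (a / sxx) / np.sqrt(rss_full / (sxx * df))
        t_star = np.clip(t_star, -T_SENTINEL, T_SENTINEL)
        max_null[b] = np.abs(t_star).max() if tails == 2 else (-t_star).max()
    return max_null


def fwe_threshold(
    stats_map: VoxelStatMap,
    design: DesignMatrix,
    fuzzies,
    mask: AnalysisMask,
    alpha: float = 0.05,
    method: str = "permutation_maxT",
    n_perm: int = 2000,
    seed: int | None = None,
    tails: int = 1,
) -> RoiMask:
    """Family-wise-error corrected ROI at voxel-level alpha.

    ``method='permutation_maxT'`` uses Freedman-Lane residual permutation of
    the regressor of interest and thresholds at the (1 - alpha) quantile of
    the max-statistic null; ``method='bonferroni'`` uses the t quantile at
    alpha / n_voxels. The ROI keeps voxels with the hypothesised negative
    sign whose statistic magnitude reaches the threshold (``tails=2`` drops
    the sign restriction).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    t = stats_map.t_values
    df = stats_map.df

    if method == "bonferroni":
        per_voxel = alpha / mask.n_voxels
        threshold = float(stats.t.ppf(1.0 - per_voxel / tails, df))
    elif method == "permutation_maxT":
        if n_perm < 500:
            raise ValueError("n_perm >= 500 required for stable FWE control")
        if n_perm < 1.0 / alpha:
            raise ValueError(
                f"n_perm={n_perm} cannot resolve alpha={alpha}; "
                f"need at least {int(np.ceil(1 / alpha))} permutations"
            )
        if seed is None:
            raise ValueError("permutation method requires a seed")
        rng = np.random.default_rng(seed)
        y = _masked_data(fuzzies, mask)
        max_null = _freedman_lane_max_null(y, design, n_perm, rng, tails)
        # conservative finite-sample quantile (includes the observed ordering)
        rank = int(np.ceil((1.0 - alpha) * (n_perm + 1))) - 1
        threshold = float(np.sort(max_null)[min(rank, n_perm - 1)])
    else:
        raise ValueError(f"unknown FWE method: {method!r}")

    if tails == 1:
        selected = (-t) >= threshold  # hypothesised negative direction
    else:
        selected = np.abs(t) >= threshold
    sel_idx = np.argwhere(stats_map.mask.in_mask)[selected]
    return RoiMask(voxels=sel_idx, threshold_used=threshold, method=method,
                   grid_shape=mask.in_mask.shape, alpha=alpha)


def extract_lesion_load(fuzzies, roi: RoiMask) -> np.ndarray:
    """Mean fuzzy abnormality over the ROI, one value per patient."""
    if roi.n_voxels == 0:
        raise ValueError("cannot compute lesion load for an empty ROI")
    data = stack_values(fuzzies)
    return data[:, roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]].mean(axis=1)
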