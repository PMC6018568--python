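"""Bootstrap reproducibility study of the ROI lesion-deficit effect.

A fixed cohort is resampled (with replacement by default) at a ladder of
sample sizes; for every resample the partial correlation between ROI lesion
load and the target score given the five covariates is recorded as
(R-squared, p, sign). Summaries mirror the reproducibility questions:
how often the effect reaches significance, how inflated the significant
estimates are (winner's curse), how the estimates fall against the
full-cohort credible interval, and which resamples sit at each decile of
the effect-size distribution.

Randomness uses one master seed with a per-(size, replicate) substream, so
any single resample can be reproduced in isolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import COVARIATE_COLUMNS, SCORE_COLUMNS
from .effects import CredibleInterval, analytic_power
from .glm import DesignMatrix
from .lesion_io import stack_values

__all__ = [
    "draw_bootstrap_indices",
    "record_indices",
    "run_resampling_study",
    "summarize_by_significance",
    "classify_against_interval",
    "select_decile_resamples",
    "roi_power_summary",
]

DEFAULT_SIZES = (30, 60, 90, 120, 180, 360)
_N_COVARIATES = 5


def draw_bootstrap_indices(n_total, size, with_replacement, rng):
    """Indices of one resample: i.i.d. uniform or a uniform subset."""
    if size < 0:
        raise ValueError("size must be non-negative")
    if with_replacement:
        return rng.integers(0, n_total, size=size)
    if size > n_total:
        raise ValueError(
            f"cannot draw {size} from {n_total} without replacement")
    return rng.permutation(n_total)[:size]


def _record_seed(seed: int, size: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(size, replicate))


def record_indices(seed, n_total, size, replicate, with_replacement=True):
    """Reproduce the index list of one (size, replicate) record in isolation."""
    rng = np.random.default_rng(_record_seed(seed, size, replicate))
    return draw_bootstrap_indices(n_total, size, with_replacement, rng)


def _batched_partial_stats(y, x, c, idx):
    """Vectorised partial correlation over a batch of resample index rows.

    Returns (r, ok) where ``ok`` flags records whose covariate matrix was
    numerically full rank and whose residuals were non-degenerate.
    """
    b, s = idx.shape
    z = np.concatenate(
        [np.ones((b, s, 1)), c[idx]], axis=2)  # (b, s, 6)
    ys = y[idx]
    xs = x[idx]
    g = np.einsum("bij,bik->bjk", z, z)
    zty = np.einsum("bij,bi->bj", z, ys)
    ztx = np.einsum("bij,bi->bj", z, xs)
    ok = np.linalg.cond(g) < 1e10
    g_safe = np.where(ok[:, None, None], g, np.eye(z.shape[2]))
    beta_y = np.linalg.solve(g_safe, zty[..., None])[..., 0]
    beta_x = np.linalg.solve(g_safe, ztx[..., None])[..., 0]
    ry = ys - np.einsum("bij,bj->bi", z, beta_y)
    rx = xs - np.einsum("bij,bj->bi", z, beta_x)
    syy = np.einsum("bi,bi->b", ry, ry)
    sxx = np.einsum("bi,bi->b", rx, rx)
    sxy = np.einsum("bi,bi->b", ry, rx)
    ok &= (syy > 1e-16) & (sxx > 1e-16)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sxy / np.sqrt(syy * sxx)
    r = np.clip(r, -1.0, 1.0)
    return r, ok


def _pvalues(r, size):
    from scipy import stats

    df = size - 2 - _N_COVARIATES
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def run_resampling_study(
    cohort: pd.DataFrame,
    lesion_load: np.ndarray,
    sizes=DEFAULT_SIZES,
    B: int = 6000,
    with_replacement: bool = True,
    seed: int | None = None,
    chunk: int = 1000,
) -> pd.DataFrame:
    """Resample the fixed cohort and record (size, replicate, r2, p, sign).

    Rank-deficient resamples are redrawn from a child substream and counted;
    more than 1% redraws at any size aborts with a diagnostic (it indicates
    a degenerate cohort rather than bad luck).
    """
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if B < 1:
        raise ValueError("B must be >= 1")
    y = cohort[SCORE_COLUMNS[0]].to_numpy(dtype=float)
    c = cohort.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    x = np.asarray(lesion_load, dtype=float)
    n_total = len(cohort)
    min_size = _N_COVARIATES + 3
    frames = []
    for size in sizes:
        if size < min_size:
            raise ValueError(f"resample size {size} leaves no degrees of freedom")
        idx = np.empty((B, size), dtype=np.intp)
        for rep in range(B):
            rng = np.random.default_rng(_record_seed(seed, size, rep))
            idx[rep] = draw_bootstrap_indices(n_total, size, with_replacement, rng)
        r = np.empty(B)
        ok = np.zeros(B, dtype=bool)
        for start in range(0, B, chunk):
            sl = slice(start, min(start + chunk, B))
            r[sl], ok[sl] = _batched_partial_stats(y, x, c, idx[sl])
        n_redraw = 0
        for rep in np.nonzero(~ok)[0]:
            child = _record_seed(seed, size, rep).spawn(1)[0]
            rng = np.random.default_rng(child)
            for _ in range(100):
                n_redraw += 1
                new_idx = draw_bootstrap_indices(n_total, size, with_replacement, rng)
                rr, rok = _batched_partial_stats(y, x, c, new_idx[None, :])
                if rok[0]:
                    r[rep] = rr[0]
                    break
            else:
                raise RuntimeError(
                    f"persistent rank deficiency at size {size}, replicate {rep}")
        if n_redraw > 0.01 * B:
            raise RuntimeError(
                f"{n_redraw} redraws at size {size} (> 1% of {B}): "
                "cohort covariates appear degenerate")
        p = _pvalues(r, size)
        frames.append(pd.DataFrame({
            "size": size,
            "replicate": np.arange(B),
            "r2": r * r,
            "p": p,
            "sign": np.where(r >= 0, 1, -1).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def summarize_by_significance(records: pd.DataFrame, alphas=(0.05, 0.001)) -> pd.DataFrame:
    """Count / mean / median / min / max of R² split by significance.

    One row per (size, alpha, group) with group in {significant,
    not_significant}. Empty cells keep count 0 and NaN moments (rendered as
    a dash in report tables).
    """
    if records.empty:
        raise ValueError("no resample records to summarise")
    rows = []
    for size, grp in records.groupby("size"):
        for alpha in alphas:
            sig = grp["p"] < alpha
            for label, sel in (("significant", sig), ("not_significant", ~sig)):
                r2 = grp.loc[sel, "r2"]
                rows.append({
                    "size": size, "alpha": alpha, "group": label,
                    "count": int(sel.sum()),
                    "mean_r2": r2.mean() if len(r2) else np.nan,
                    "median_r2": r2.median() if len(r2) else np.nan,
                    "min_r2": r2.min() if len(r2) else np.nan,
                    "max_r2": r2.max() if len(r2) else np.nan,
                })
    return pd.DataFrame(rows)


def classify_against_interval(
    records: pd.DataFrame, interval: CredibleInterval, alpha: float = 0.05
) -> pd.DataFrame:
    """Cross-tabulate records by significance and position vs the interval.

    Six cells per size: (significant, not significant) x (above the upper
    bound, within, below the lower bound); the cells partition the B
    records of each size.
    """
    rows = []
    for size, grp in records.groupby("size"):
        sig = grp["p"] < alpha
        above = grp["r2"] > interval.upper_r2
        below = grp["r2"] < interval.lower_r2
        within = ~above & ~below
        for label, sel in (("significant", sig), ("not_significant", ~sig)):
            rows.append({
                "size": size, "group": label,
                "above": int((sel & above).sum()),
                "within": int((sel & within).sum()),
                "below": int((sel & below).sum()),
            })
    return pd.DataFrame(rows)


def select_decile_resamples(records: pd.DataFrame) -> pd.DataFrame:
    """The actual resample sitting at each decile of the R² distribution.

    Nearest-rank (no interpolation) selection per size at the 0th, 10th,
    ..., 100th percentiles; ties in R² break towards the lowest replicate
    index. Returns one row per (size, percentile) with that record's
    replicate, r2 and p.
    """
    rows = []
    for size, grp in records.groupby("size"):
        b = len(grp)
        if b < 11:
            raise ValueError("need at least 11 records per size for deciles")
        ordered = grp.sort_values(["r2", "replicate"]).reset_index(drop=True)
        for q in range(0, 101, 10):
            rank = max(int(np.ceil(q / 100.0 * b)), 1) - 1
            rec = ordered.iloc[rank]
            rows.append({
                "size": size, "percentile": q,
                "replicate": int(rec["replicate"]),
                "r2": rec["r2"], "p": rec["p"],
            })
    return pd.DataFrame(rows)


def roi_power_summary(
    fuzzies_subset,
    design: DesignMatrix,
    roi,
    alpha_corrected: float,
    power_threshold: float = 0.80,
) -> float:
    """Percent of ROI voxels with sufficient power in one resample.

    For each ROI voxel the observed effect size is the squared partial
    correlation between that voxel's fuzzy abnormality and the target
    score given the five covariates (computed from the voxelwise GLM t
    statistic); its power to reach ``alpha_corrected`` at this resample's
    sample size comes from the Fisher-z approximation. A voxel is
    "sufficient" when that power reaches ``power_threshold``.
    """
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    from .glm import _glm_t

    data = stack_values(fuzzies_subset)
    y = data[:, roi.voxels[:, 0], roi.voxels[:, 1], roi.voxels[:, 2]]
    n = design.n
    if y.shape[0] != n:
        raise ValueError("subset volumes do not match the design matrix")
    t, df, _ = _glm_t(y, design.values, design.target_index)
    r2 = t * t / (t * t + df)
    power = np.array([
        analytic_power(min(v, 1 - 1e-12), n, _N_COVARIATES, alpha_corrected)
        for v in r2
    ])
    return float(100.0 * np.mean(power >= power_threshold))
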