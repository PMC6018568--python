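"""Synthetic lesion volume rendering.

Each patient's lesion is a single smooth blob: abnormality 1.0 inside a
core radius, decaying linearly to 0 over a ramp of configurable width. The
blob's size is set so the thresholded (binary) lesion reproduces the
patient's lesion volume in cm^3, and its position relative to the true ROI
is solved so the mean fuzzy value over the ROI equals the patient's latent
lesion load. Binary volumes are, by construction, exactly the fuzzy volume
thresholded at ``config.binary_threshold``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .lesion_io import BinaryLesionVolume, FuzzyLesionVolume

__all__ = ["generate_lesion_volumes"]

_MIN_RAMP_MM = 0.5


def _fuzzy_profile(dist: np.ndarray, r_core: float, width: float) -> np.ndarray:
    return np.clip(1.0 - (dist - r_core) / width, 0.0, 1.0)


def _discrete_radius(center, r_cont, count_target, shape, vsize):
    """Radius (mm) whose voxel-center ball holds round(count_target) voxels."""
    k = max(int(round(count_target)), 1)
    half = r_cont + 3 * vsize
    lo = np.maximum(np.floor((center - half) / vsize).astype(int), 0)
    hi = np.minimum(np.ceil((center + half) / vsize).astype(int) + 1, shape)
    idx = np.stack(np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.sort(np.linalg.norm(idx * vsize - center, axis=1))
    if k >= d.size:
        return float(d[-1] + vsize / 2.0)
    return float((d[k - 1] + d[k]) / 2.0)


def _direction_d_max(c0, u, margin, extent):
    """Largest step d keeping c0 + d*u inside [margin, extent - margin]."""
    lo = np.minimum(margin, extent / 2.0)
    hi = extent - lo
    d_max = np.inf
    for i in range(3):
        if u[i] > 1e-12:
            d_max = min(d_max, (hi[i] - c0[i]) / u[i])
        elif u[i] < -1e-12:
            d_max = min(d_max, (lo[i] - c0[i]) / u[i])
    return max(d_max, 0.0)


def _solve_offset(roi_xyz, c0, u, d_max, r_core, width, target):
    """Distance d along u with mean fuzzy over ROI equal to target."""

    def mean_f(d):
        c = c0 + d * u
        dist = np.linalg.norm(roi_xyz - c, axis=1)
        return float(_fuzzy_profile(dist, r_core, width).mean())

    grid = np.linspace(0.0, d_max, 160)
    vals = np.array([mean_f(d) for d in grid])
    below = np.nonzero(vals <= target)[0]
    if below.size == 0:
        return d_max, vals[-1]  # cannot move far enough away
    j = below[0]
    if j == 0:
        return 0.0, vals[0]
    lo, hi = grid[j - 1], grid[j]
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mean_f(mid) > target:
            lo = mid
        else:
            hi = mid
    d = 0.5 * (lo + hi)
    return d, mean_f(d)


def _shrink_ramp(roi_xyz, center, r_disc, thr, w_hi, target):
    """Steepen the ramp until the mean fuzzy over the ROI reaches target."""
    dist = np.linalg.norm(roi_xyz - center, axis=1)

    def mean_f(w):
        return float(_fuzzy_profile(dist, r_disc - (1 - thr) * w, w).mean())

    lo, hi = _MIN_RAMP_MM, w_hi
    if mean_f(lo) < target:
        return lo, mean_f(lo)  # geometrically infeasible even with a sharp edge
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mean_f(mid) < target:
            hi = mid
        else:
            lo = mid
    w = 0.5 * (lo + hi)
    return w, mean_f(w)


def generate_lesion_volumes(
    config: GeneratorConfig,
    cohort: pd.DataFrame,
    lesion_load: np.ndarray,
    seed: int | None = None,
):
    """Render per-patient fuzzy and binary lesion volumes.

    Returns ``(fuzzies, binaries, diagnostics)`` where the diagnostics dict
    reports the worst lesion-load and lesion-volume reproduction errors and
    the minimum binary overlap across true-ROI voxels.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    lesion_load = np.asarray(lesion_load, dtype=float)
    n = len(cohort)
    if lesion_load.shape != (n,):
        raise ValueError("lesion_load length must match the cohort")

    shape = np.array(config.grid_shape)
    vsize = config.voxel_size_mm
    thr = config.binary_threshold
    roi_vox = config.true_roi_voxels()
    roi_xyz = roi_vox * vsize
    roi_center = np.asarray(config.roi_center, dtype=float) * vsize
    extent = (shape - 1) * vsize
    rng = np.random.default_rng(seed)

    fuzzies, binaries = [], []
    load_errs, vol_errs = [], []
    sizes = cohort["lesion_size_cm3"].to_numpy(dtype=float)
    pids = cohort["patient_id"].astype(str).tolist()

    for i in range(n):
        target = float(lesion_load[i])
        if target <= 0.0:
            zeros = np.zeros(tuple(shape))
            fuzzies.append(FuzzyLesionVolume(zeros, vsize, patient_id=pids[i]))
            binaries.append(BinaryLesionVolume(zeros, vsize, patient_id=pids[i]))
            continue

        count_target = sizes[i] * 1000.0 / vsize**3
        r_disc = (3.0 * sizes[i] * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        center = roi_center.copy()
        width = config.edge_width_mm

        for _ in range(4):
            w_eff = min(width, 0.9 * r_disc / (1.0 - thr))
            w_eff = max(w_eff, _MIN_RAMP_MM)
            r_core = r_disc - (1.0 - thr) * w_eff
            dist0 = np.linalg.norm(roi_xyz - roi_center, axis=1)
            m0 = float(_fuzzy_profile(dist0, r_core, w_eff).mean())
            if m0 < target - 1e-4:
                # blob on top of the ROI still too faint: steepen the edge
                w_eff, _ = _shrink_ramp(roi_xyz, roi_center, r_disc, thr,
                                        w_eff, target)
                r_core = r_disc - (1.0 - thr) * w_eff
                center = roi_center.copy()
            else:
                d_max = _direction_d_max(roi_center, u, r_disc, extent)
                d, achieved = _solve_offset(roi_xyz, roi_center, u, d_max,
                                            r_core, w_eff, target)
                if achieved > target + 5e-3:
                    # not enough room along this direction; try the best of a few
                    best = (d, achieved, u)
                    for _try in range(8):
                        u2 = rng.standard_normal(3)
                        u2 /= np.linalg.norm(u2)
                        d2_max = _direction_d_max(roi_center, u2, r_disc, extent)
                        d2, a2 = _solve_offset(roi_xyz, roi_center, u2, d2_max,
                                               r_core, w_eff, target)
                        if abs(a2 - target) < abs(best[1] - target):
                            best = (d2, a2, u2)
                        if a2 <= target + 5e-3:
                            break
                    d, achieved, u = best
                center = roi_center + d * u
            r_new = _discrete_radius(center, r_disc, count_target, shape, vsize)
            if abs(r_new - r_disc) < 0.05:
                r_disc = r_new
                break
            r_disc = r_new

        r_core = r_disc - (1.0 - thr) * w_eff
        # render into a local bounding box
        reach = r_core + w_eff
        lo = np.maximum(np.floor((center - reach) / vsize).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((center + reach) / vsize).astype(int) + 2, shape)
        grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)],
                            indexing="ij")
        xyz = np.stack(grids, axis=-1) * vsize
        dist = np.linalg.norm(xyz - center, axis=-1)
        fvals = np.zeros(tuple(shape))
        fvals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = _fuzzy_profile(
            dist, r_core, w_eff)
        bvals = (fvals >= thr).astype(np.uint8)

        f_roi = float(fvals[roi_vox[:, 0], roi_vox[:, 1], roi_vox[:, 2]].mean())
        load_errs.append(abs(f_roi - target))
        vol = bvals.sum() * vsize**3 / 1000.0
        vol_errs.append(abs(vol - sizes[i]) / sizes[i])

        fuzzies.append(FuzzyLesionVolume(fvals, vsize, patient_id=pids[i]))
        binaries.append(BinaryLesionVolume(bvals, vsize, patient_id=pids[i]))

    overlap_roi = np.zeros(len(roi_vox), dtype=int)
    for b in binaries:
        overlap_roi += b.values[roi_vox[:, 0], roi_vox[:, 1], roi_vox[:, 2]]
    min_overlap_roi = int(overlap_roi.min()) if len(binaries) else 0
    if n >= 90 and min_overlap_roi < config.min_overlap:
        warnings.warn(
            f"true-ROI voxel overlap fell to {min_overlap_roi} "
            f"(< {config.min_overlap}); the ROI may not be discoverable"
        )

    diagnostics = {
        "max_load_error": float(max(load_errs)) if load_errs else 0.0,
        "max_volume_rel_error": float(max(vol_errs)) if vol_errs else 0.0,
        "min_true_roi_overlap": min_overlap_roi,
    }
    return fuzzies, binaries, diagnostics
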