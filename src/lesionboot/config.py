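"""Configuration objects for the synthetic cohort generator and study runs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["GeneratorConfig", "StudyConfig", "CalibratedEffect"]

#: Column order of the behavioural scores in a cohort table. The first
#: entry is the target score (nonword repetition); the remaining four are
#: the nuisance covariates.
SCORE_COLUMNS = ("score_repn", "score_wpn", "score_sema", "score_recm", "score_awp")
COVARIATE_COLUMNS = SCORE_COLUMNS[1:] + ("lesion_size_cm3",)


def _default_covariate_corr() -> np.ndarray:
    """Latent correlation among (4 nuisance scores, log lesion size).

    Behavioural deficits co-occur moderately (0.4 between scores) and all
    worsen with larger lesions (-0.35 with log lesion size). The published
    covariance of the real scores is unknown; these are documented defaults.
    """
    r = np.full((5, 5), 0.4)
    np.fill_diagonal(r, 1.0)
    r[:4, 4] = r[4, :4] = -0.35
    return r


def _lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class CalibratedEffect:
    """Effect coefficients fixed by :func:`lesionboot.synthetic.calibrate_generator`.

    The target score (standardised) is generated as

        y* = beta * (L - load_mc_mean) / load_mc_sd
             + gamma * sum(standardised nuisance scores) + eps,

    with ``eps ~ N(0, noise_sd**2)``. ``beta`` and ``noise_sd`` are solved so
    that the population squared partial correlation between ROI lesion load
    ``L`` and the target score, given the four nuisance scores and lesion
    size, equals the configured target, and Var(y*) = 1.
    """

    beta: float
    gamma: float
    noise_sd: float
    load_mc_mean: float
    load_mc_sd: float
    load_resid_var: float  # residual variance of standardised load given covariates
    target_partial_r2: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic lesion-deficit cohort generator.

    Behavioural scores are T-scores (population mean 50, SD 10, clipped to
    ``score_clip``); lesion sizes are cm^3 from a clipped lognormal whose
    unclipped moments match the study population (mean 85.7, SD 87.6,
    range 1.5-386.2); lesion volumes live on a regular voxel grid with a
    spherical "true" ROI whose mean fuzzy abnormality is the latent lesion
    load driving the target deficit.
    """

    n_patients: int = 360
    target_partial_r2: float = 0.11
    effect_sign: int = -1
    covariate_corr: np.ndarray = field(default_factory=_default_covariate_corr)
    score_mean: float = 50.0
    score_sd: float = 10.0
    score_clip: tuple[float, float] = (10.0, 90.0)
    lesion_size_lognormal_params: tuple[float, float] = _lognormal_from_moments(85.7, 87.6)
    lesion_size_range: tuple[float, float] = (1.5, 386.2)
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    roi_center_vox: tuple[int, int, int] | None = None
    roi_radius_mm: float = 6.0
    binary_threshold: float = 0.3
    seed: int | None = None

    # latent structure linking ROI lesion load to the other variables
    load_mean: float = 0.35
    load_sd: float = 0.15
    load_clip: tuple[float, float] = (0.005, 0.995)
    load_size_corr: float = 0.65
    load_nuisance_corr: float = -0.30
    nuisance_weight: float = 0.15
    # lesion geometry: width (mm) of the fuzzy ramp from core (1.0) to 0;
    # shallow enough that single-voxel abnormality tracks the ROI-mean load
    edge_width_mm: float = 24.0
    min_overlap: int = 5
    # impairment cut-offs from the behavioural battery; metadata only,
    # never used in inference
    impairment_cutoff_t: float = 40.0

    calibration: CalibratedEffect | None = None

    def __post_init__(self):
        c = np.asarray(self.covariate_corr, dtype=float)
        object.__setattr__(self, "covariate_corr", c)
        if c.shape != (5, 5) or not np.allclose(c, c.T):
            raise ValueError("covariate_corr must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("covariate_corr must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("covariate_corr is not positive semi-definite")
        if not 0 <= self.target_partial_r2 < 1:
            raise ValueError("target_partial_r2 must be in [0, 1)")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be -1 or +1")
        if not 0 < self.binary_threshold < 1:
            raise ValueError("binary_threshold must be in (0, 1)")
        if self.lesion_size_range[0] < 1.5:
            raise ValueError(
                "lesion_size_range minimum below 1.5 cm^3 violates the "
                "cohort inclusion rule (lesions greater than 1 cm^3 only; "
                "smallest retained lesion 1.5 cm^3)"
            )

    # ------------------------------------------------------------------
    @property
    def roi_center(self) -> tuple[int, int, int]:
        if self.roi_center_vox is not None:
            return tuple(self.roi_center_vox)
        return tuple(int(s // 2) for s in self.grid_shape)

    def true_roi_voxels(self) -> np.ndarray:
        """(m, 3) integer voxel indices of the designated true ROI."""
        center = np.asarray(self.roi_center, dtype=float)
        grids = np.indices(self.grid_shape).reshape(3, -1).T
        d = np.linalg.norm((grids - center) * self.voxel_size_mm, axis=1)
        vox = grids[d <= self.roi_radius_mm]
        if vox.size == 0:
            raise ValueError("true ROI contains no voxels on this grid")
        if (vox.min() < 0) or np.any(vox.max(axis=0) >= np.array(self.grid_shape)):
            raise ValueError("true ROI extends outside the grid")
        return vox

    def joint_latent_corr(self) -> np.ndarray:
        """6x6 latent correlation of (load, 4 nuisance scores, log size)."""
        full = np.empty((6, 6))
        full[1:, 1:] = self.covariate_corr
        full[0, 0] = 1.0
        full[0, 1:5] = full[1:5, 0] = self.load_nuisance_corr
        full[0, 5] = full[5, 0] = self.load_size_corr
        if np.linalg.eigvalsh(full).min() < -1e-10:
            raise ValueError(
                "joint latent correlation (load + covariates) is not PSD; "
                "adjust load_size_corr / load_nuisance_corr / covariate_corr"
            )
        return full

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_corr"] = self.covariate_corr.tolist()
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        calib = d.pop("calibration", None)
        for key in ("score_clip", "lesion_size_lognormal_params", "lesion_size_range",
                    "grid_shape", "roi_center_vox", "load_clip"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        if calib is not None:
            cfg = cfg.replace(calibration=CalibratedEffect(**calib))
        return cfg


@dataclass(frozen=True)
class StudyConfig:
    """End-to-end study settings: generation, ROI analysis, resampling."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_overlap: int = 5
    fwe_method: str = "permutation_maxT"
    alpha_voxel: float = 0.05
    n_perm: int = 1000
    sizes: tuple[int, ...] = (30, 60, 90, 120, 180, 360)
    n_boot: int = 6000
    with_replacement: bool = True
    alphas: tuple[float, ...] = (0.05, 0.001)
    seed: int = 0
    skip_imaging: bool = False
    output_dir: str = "study_output"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required for a reproducible study")
        for s in self.sizes:
            if self.generator.n_patients % s:
                raise ValueError(
                    f"resample size {s} does not divide the cohort size "
                    f"{self.generator.n_patients} evenly"
                )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        d = yaml.safe_load(Path(path).read_text())
        gen = d.pop("generator", None)
        if gen is not None:
            gen.pop("calibration", None)
            for key in ("score_clip", "lesion_size_lognormal_params",
                        "lesion_size_range", "grid_shape", "roi_center_vox",
                        "load_clip"):
                if gen.get(key) is not None:
                    gen[key] = tuple(gen[key])
            d["generator"] = GeneratorConfig(**gen)
        for key in ("sizes", "alphas"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)
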