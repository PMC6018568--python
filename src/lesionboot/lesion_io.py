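"""NIfTI lesion-volume I/O, overlap maps and analysis masks.

All cross-patient operations require byte-identical affines: the images are
assumed to already live in one standard space, and no resampling is ever
performed. Voxel coordinates are 0-based array indices; world coordinates
come from the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FuzzyLesionVolume",
    "BinaryLesionVolume",
    "OverlapMap",
    "AnalysisMask",
    "load_volumes",
    "save_volume",
    "build_overlap_map",
    "make_analysis_mask",
    "stack_values",
]


def _default_affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


@dataclass
class FuzzyLesionVolume:
    """Continuous structural-abnormality map, 0 (normal) to 1 (abnormal)."""

    values: np.ndarray
    voxel_size_mm: float
    patient_id: str = ""
    space_id: str = "synthetic"
    affine: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("lesion volumes must be 3-D")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError(
                f"fuzzy values outside [0, 1] for patient {self.patient_id!r}"
            )
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)


@dataclass
class BinaryLesionVolume:
    """Thresholded (lesion / no lesion) version of a fuzzy lesion image."""

    values: np.ndarray
    voxel_size_mm: float
    patient_id: str = ""
    affine: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("lesion volumes must be 3-D")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(
                f"binary values outside {{0, 1}} for patient {self.patient_id!r}"
            )
        self.values = self.values.astype(np.uint8)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)

    @property
    def lesion_volume_cm3(self) -> float:
        return float(self.values.sum()) * self.voxel_size_mm**3 / 1000.0


@dataclass
class OverlapMap:
    """Voxelwise count of patients whose binary lesion covers each voxel."""

    counts: np.ndarray
    voxel_size_mm: float
    n_patients: int
    affine: np.ndarray = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)


@dataclass
class AnalysisMask:
    """Voxels damaged in at least ``min_patients`` patients."""

    in_mask: np.ndarray
    min_patients: int
    voxel_size_mm: float = 1.0
    affine: np.ndarray = None
    n_voxels: int = field(init=False)

    def __post_init__(self):
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        self.n_voxels = int(self.in_mask.sum())
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)


# ----------------------------------------------------------------------
def save_volume(volume, path) -> None:
    """Write a lesion volume, overlap map or mask as NIfTI-1."""
    if isinstance(volume, FuzzyLesionVolume):
        data = volume.values.astype(np.float32)
    elif isinstance(volume, BinaryLesionVolume):
        data = volume.values.astype(np.uint8)
    elif isinstance(volume, OverlapMap):
        data = volume.counts.astype(np.int32)
    elif isinstance(volume, AnalysisMask):
        data = volume.in_mask.astype(np.uint8)
    else:
        raise TypeError(f"cannot save object of type {type(volume).__name__}")
    nib.save(nib.Nifti1Image(data, volume.affine), str(path))


def load_volumes(paths, kind: str):
    """Load a set of lesion volumes from NIfTI files.

    Parameters
    ----------
    paths : sequence of path-like
        NIfTI files, one per patient. All must share grid shape and affine.
    kind : {"fuzzy", "binary"}
        Value range to enforce: [0, 1] for fuzzy, {0, 1} for binary.
    """
    if kind not in ("fuzzy", "binary"):
        raise ValueError("kind must be 'fuzzy' or 'binary'")
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no volume files given")
    volumes = []
    ref_shape = ref_affine = None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, img.affine
        else:
            if data.shape != ref_shape or not np.array_equal(img.affine, ref_affine):
                raise ValueError(f"grid/affine mismatch in {p.name}")
        vsize = float(np.abs(np.diag(img.affine)[:3]).mean())
        pid = p.name.split(".")[0]
        try:
            if kind == "fuzzy":
                volumes.append(FuzzyLesionVolume(data, vsize, patient_id=pid,
                                                affine=img.affine))
            else:
                volumes.append(BinaryLesionVolume(data, vsize, patient_id=pid,
                                                  affine=img.affine))
        except ValueError as err:
            raise ValueError(f"{p.name}: {err}") from err
    return volumes


def stack_values(volumes) -> np.ndarray:
    """(n_patients, *grid) array from a list of volumes (shared grid required)."""
    shapes = {v.values.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError("volumes are not on a common grid")
    return np.stack([np.asarray(v.values, dtype=np.float64) for v in volumes])


def build_overlap_map(binaries) -> OverlapMap:
    """Voxelwise sum of binary lesion images across patients."""
    binaries = list(binaries)
    if not binaries:
        raise ValueError("cannot build an overlap map from an empty volume set")
    counts = stack_values(binaries).sum(axis=0).astype(np.int32)
    return OverlapMap(
        counts=counts,
        voxel_size_mm=binaries[0].voxel_size_mm,
        n_patients=len(binaries),
        affine=binaries[0].affine,
    )


def make_analysis_mask(overlap: OverlapMap, min_patients: int = 5) -> AnalysisMask:
    """Restrict analysis to voxels damaged in at least ``min_patients`` patients."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    in_mask = overlap.counts >= min_patients
    if not in_mask.any():
        raise ValueError("no analyzable voxels: overlap never reaches min_patients")
    return AnalysisMask(in_mask=in_mask, min_patients=min_patients,
                        voxel_size_mm=overlap.voxel_size_mm, affine=overlap.affine)
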