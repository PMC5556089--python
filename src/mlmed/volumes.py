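"""Volumetric and tabular plumbing: grids, affines, sphere ROIs, readers/writers.

Voxel indices are 0-based internally; every user-facing coordinate is in
millimetres (MNI convention for real data).  NIfTI volumes follow the RAS+
convention of nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with a 4x4 voxel-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # 4x4, maps voxel indices (homogeneous) to mm

    def __post_init__(self):
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular (not invertible)")
        object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def contains(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.shape)))


@dataclass(frozen=True)
class SphereRoi:
    """Voxel membership of a sphere defined in mm space."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    voxels: np.ndarray = field(repr=False)  # (n, 3) int indices

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def isotropic_grid(shape, voxel_size_mm: float = 2.0, origin_mm=(0.0, 0.0, 0.0)) -> VolumeGrid:
    """Convenience constructor: axis-aligned isotropic grid.

    ``origin_mm`` is the mm coordinate of voxel (0, 0, 0).
    """
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[:3, 3] = origin_mm
    return VolumeGrid(tuple(shape), aff)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def voxel_to_mm(ijk, grid: VolumeGrid) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    mm = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return mm[0] if mm.shape[0] == 1 else mm

def mm_to_voxel(center_mm, grid: VolumeGrid) -> tuple[int, int, int]:
    """Nearest voxel index of an mm coordinate (round half away from zero).

    Raises ``ValueError`` when the rounded index falls outside the grid.
    """
    xyz1 = np.append(np.asarray(center_mm, dtype=float), 1.0)
    ijk = (grid.inverse_affine @ xyz1)[:3]
    idx = _round_half_away(ijk).astype(int)
    if not grid.contains(idx):
        raise ValueError(f"mm coordinate {tuple(center_mm)} maps to voxel {tuple(idx)} "
                         f"outside grid of shape {grid.shape}")
    return tuple(int(v) for v in idx)


def make_sphere(center_mm, radius_mm: float, grid: VolumeGrid) -> SphereRoi:
    """All voxels whose *center* lies within ``radius_mm`` of ``center_mm``.

    Membership is evaluated in mm space through the grid affine, so the result
    is invariant under a consistent translation of both volume and center.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    d2 = np.sum((mm - np.asarray(center_mm, dtype=float)) ** 2, axis=1)
    members = ijk[d2 <= radius_mm ** 2]
    if members.shape[0] == 0:
        raise ValueError(f"sphere at {tuple(center_mm)} (r={radius_mm} mm) contains no voxel")
    return SphereRoi(tuple(float(c) for c in center_mm), float(radius_mm), members)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_volume(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float)), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_events(path, table: pd.DataFrame) -> None:
    """Write a BIDS-style events table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_motion(path, motion: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.10g")


def read_motion(path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if not np.all(np.isfinite(m)):
        raise ValueError(f"non-finite values in motion file {path}")
    return m


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
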