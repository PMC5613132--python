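"""Volumetric containers, NIfTI I/O, affine geometry, and map algebra.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)``;
* world space is RAS millimetres, obtained as ``affine @ (i, j, k, 1)``;
* the left hemisphere lives at world ``x < 0``;
* "suprathreshold" always means strictly ``Z > threshold``.

:class:`StatMap` is the shared in-memory representation of a subject's
voxelwise Z (or beta/contrast) image; every downstream stage (laterality
indices, pattern graphs, peak localization, connectivity contrasts)
consumes and produces it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

MAP_KINDS = ("zstat", "beta", "contrast")
SIDES = ("left", "right", "none")


class ValidationError(ValueError):
    """Raised when volumetric data violates a container invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a voxel grid."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValidationError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is singular")
    return affine


@dataclass(frozen=True)
class StatMap:
    """A 3-D statistical map on a regular grid with an RAS affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    map_kind: str = "zstat"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValidationError(f"StatMap data must be 3-D, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValidationError(f"grid dimensions must be positive, got {data.shape}")
        n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
        if n_bad:
            raise ValidationError(f"map contains {n_bad} non-finite voxels")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", _check_affine(self.affine))
        if self.map_kind not in MAP_KINDS:
            raise ValidationError(f"map_kind must be one of {MAP_KINDS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths in mm along each grid axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray, **kw) -> "StatMap":
        return replace(self, data=data, **kw)

    def same_grid(self, other: "StatMap") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask on a map grid."""

    data: np.ndarray
    side: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data.astype(bool)
        if data.ndim != 3:
            raise ValidationError("RoiMask data must be 3-D")
        if not data.any():
            raise ValidationError(f"RoiMask {self.label!r} is empty")
        object.__setattr__(self, "data", data)
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class RoiPair:
    """Disjoint left/right masks (paired ROIs or whole hemispheres)."""

    left: RoiMask
    right: RoiMask

    def __post_init__(self) -> None:
        if self.left.side != "left" or self.right.side != "right":
            raise ValidationError("RoiPair sides must be ('left', 'right')")
        if self.left.data.shape != self.right.data.shape:
            raise GridMismatchError("RoiPair masks are on different grids")
        if np.any(self.left.data & self.right.data):
            raise ValidationError("RoiPair masks overlap")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> StatMap:
    """Read a 3-D NIfTI-1 volume into a :class:`StatMap`.

    Raises :class:`FormatError` on unreadable files and
    :class:`ValidationError` (reporting the count) on non-finite voxels.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except ValidationError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path} is {data.ndim}-D; use restconn.read_run for 4-D runs"
        )
    n_bad = int(np.size(data) - np.count_nonzero(np.isfinite(data)))
    if n_bad:
        raise ValidationError(f"{path} contains {n_bad} non-finite voxels")
    return StatMap(data=data, affine=np.asarray(img.affine, dtype=float))


def write_volume(statmap: StatMap, path) -> None:
    """Write a :class:`StatMap` as NIfTI-1 (float64, bit-exact round trip)."""
    img = nib.Nifti1Image(statmap.data.astype(np.float64), statmap.affine)
    nib.save(img, str(path))


def read_mask(path, side: str = "none", label: str = "") -> RoiMask:
    """Read a binary mask volume (any nonzero voxel is in the mask)."""
    vol = read_volume(path)
    return RoiMask(data=vol.data != 0, side=side, label=label or str(path))


def write_mask(mask: RoiMask, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _check_affine(affine))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Affine geometry
# ---------------------------------------------------------------------------

def voxel_to_mm(index, affine: np.ndarray, shape=None) -> np.ndarray:
    """World mm coordinates of a 0-based voxel index.

    If ``shape`` is given the index is bounds-checked against the grid.
    """
    affine = _check_affine(affine)
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("index must be a length-3 (i, j, k) triple")
    if shape is not None:
        ii = np.asarray(index)
        if np.any(ii < 0) or np.any(ii >= np.asarray(shape)):
            raise IndexError(f"voxel index {tuple(index)} outside grid {tuple(shape)}")
    return affine[:3, :3] @ idx + affine[:3, 3]


def mm_to_voxel(xyz, affine: np.ndarray) -> np.ndarray:
    """Continuous voxel coordinates of a world mm point (inverse affine)."""
    affine = _check_affine(affine)
    return np.linalg.solve(affine[:3, :3], np.asarray(xyz, dtype=float) - affine[:3, 3])


def hemisphere_masks_from_affine(shape, affine: np.ndarray) -> RoiPair:
    """Left/right hemisphere masks by the sign of each voxel centre's world x.

    Voxels whose centre lies exactly on x = 0 belong to neither mask.
    """
    affine = _check_affine(affine)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    x = (affine[0, 0] * ii + affine[0, 1] * jj + affine[0, 2] * kk + affine[0, 3])
    return RoiPair(
        left=RoiMask(data=x < 0, side="left", label="hemisphere_left"),
        right=RoiMask(data=x > 0, side="right", label="hemisphere_right"),
    )


def mask_volume_mm3(n_voxels: int, affine: np.ndarray) -> float:
    """Physical volume of ``n_voxels`` voxels on the grid defined by ``affine``."""
    affine = _check_affine(affine)
    return float(n_voxels) * abs(float(np.linalg.det(affine[:3, :3])))


# ---------------------------------------------------------------------------
# Map algebra
# ---------------------------------------------------------------------------

def flip_x(statmap: StatMap) -> StatMap:
    """Mirror a map across the sagittal midline by reversing the first grid axis.

    The affine is left untouched, so this equals a world-space x-mirror
    exactly when the x = 0 plane bisects the grid (true for the synthetic
    group grid).  Applying it twice is the identity.
    """
    return statmap.with_data(statmap.data[::-1, :, :].copy())


def flip_mask_x(mask: RoiMask) -> RoiMask:
    flipped_side = {"left": "right", "right": "left", "none": "none"}[mask.side]
    return RoiMask(data=mask.data[::-1, :, :].copy(), side=flipped_side, label=mask.label)


def conjunction_min(map_a: StatMap, map_b: StatMap) -> StatMap:
    """Minimum-statistic conjunction: voxelwise min of two maps.

    Significant only where both effects are present.
    """
    if not map_a.same_grid(map_b):
        raise GridMismatchError(
            f"conjunction requires a shared grid: {map_a.shape} vs {map_b.shape}"
        )
    return map_a.with_data(np.minimum(map_a.data, map_b.data), map_kind="contrast")


def gaussian_smooth(statmap: StatMap, fwhm_mm: float) -> StatMap:
    """Gaussian smoothing with kernel width given as FWHM in mm.

    sigma = fwhm / (2 * sqrt(2 ln 2)) per axis, converted to voxels from the
    affine.  Requires isotropic voxels.  Edges use nearest replication, so a
    constant map stays constant and interior-supported mass is conserved.
    """
    if not fwhm_mm > 0:
        raise ValueError("fwhm_mm must be positive")
    sizes = statmap.voxel_sizes
    if not np.allclose(sizes, sizes[0], rtol=1e-6):
        raise ValueError(f"anisotropic voxels {sizes} are not supported")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / sizes[0]
    return statmap.with_data(ndimage.gaussian_filter(statmap.data, sigma_vox, mode="nearest"))


@dataclass(frozen=True)
class ClusterSet:
    """Connected suprathreshold components, labelled 1..K by descending size."""

    labels: np.ndarray
    sizes: np.ndarray
    peak_z: np.ndarray
    peak_index: np.ndarray  # (K, 3) voxel indices of per-cluster maxima
    affine: np.ndarray
    z_thr: float
    min_extent: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def to_table(self) -> pd.DataFrame:
        """Cluster table: id, extent, peak Z, peak mm coordinates."""
        rows = []
        for c in range(self.n_clusters):
            xyz = voxel_to_mm(self.peak_index[c], self.affine)
            rows.append(
                {
                    "cluster_id": c + 1,
                    "n_voxels": int(self.sizes[c]),
                    "peak_z": float(self.peak_z[c]),
                    "peak_x_mm": xyz[0],
                    "peak_y_mm": xyz[1],
                    "peak_z_mm": xyz[2],
                }
            )
        return pd.DataFrame(
            rows,
            columns=["cluster_id", "n_voxels", "peak_z", "peak_x_mm", "peak_y_mm", "peak_z_mm"],
        )


def label_clusters(statmap: StatMap, z_thr: float, min_extent: int = 1) -> ClusterSet:
    """Label 26-connected components of {Z > z_thr}, dropping small ones.

    Components with fewer than ``min_extent`` voxels are removed; survivors
    are relabelled 1..K by descending size (ties broken by original label).
    This is plain extent filtering, not a random-field cluster correction.
    """
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    raw, n_raw = ndimage.label(statmap.data > z_thr, structure=structure)
    out = np.zeros_like(raw)
    if n_raw == 0:
        return ClusterSet(out, np.zeros(0, int), np.zeros(0), np.zeros((0, 3), int),
                          statmap.affine, z_thr, min_extent)
    raw_sizes = np.bincount(raw.ravel())[1:]  # skip background
    keep = [lab for lab in range(1, n_raw + 1) if raw_sizes[lab - 1] >= min_extent]
    keep.sort(key=lambda lab: (-raw_sizes[lab - 1], lab))
    sizes, peaks, peak_idx = [], [], []
    for new, lab in enumerate(keep, start=1):
        where = raw == lab
        out[where] = new
        sizes.append(int(raw_sizes[lab - 1]))
        masked = np.where(where, statmap.data, -np.inf)
        flat = int(np.argmax(masked))
        peak_idx.append(np.unravel_index(flat, statmap.shape))
        peaks.append(float(statmap.data[peak_idx[-1]]))
    return ClusterSet(
        labels=out,
        sizes=np.asarray(sizes, dtype=int),
        peak_z=np.asarray(peaks, dtype=float),
        peak_index=np.asarray(peak_idx, dtype=int),
        affine=statmap.affine,
        z_thr=float(z_thr),
        min_extent=int(min_extent),
    )
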