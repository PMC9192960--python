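"""Spherical seed regions in MNI space and time-series extraction.

The default seed set covers the arbitration system (ventrolateral
prefrontal cortex, frontopolar cortex), the habitual system (SMA,
posterolateral putamen) and the goal-directed system (caudate, OFC).
Two separate left posterolateral putamen seeds (A and B) are kept as
distinct ROIs.  Coordinates are RAS millimetres in MNI space; voxel
indices are 0-based.  A voxel belongs to a sphere when its *center*
lies within the radius (no partial-volume weighting).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import BoldTimeSeries

__all__ = [
    "RoiSpec",
    "RoiSet",
    "DEFAULT_ROI_SET",
    "mm_to_voxel",
    "voxel_to_mm",
    "sphere_mask",
    "extract_roi_timeseries",
]


@dataclass(frozen=True)
class RoiSpec:
    """A spherical region of interest: label, MNI center (mm), radius (mm)."""

    label: str
    center: tuple[float, float, float]
    radius: float = 5.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI {self.label!r}: radius must be positive")
        if len(self.center) != 3:
            raise ValueError(f"ROI {self.label!r}: center must be an (x, y, z) triplet")


class RoiSet:
    """Ordered collection of :class:`RoiSpec` with unique labels."""

    def __init__(self, rois: list[RoiSpec]):
        labels = [r.label for r in rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        self.rois = list(rois)

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.rois:
                if r.label == key:
                    return r
            raise KeyError(key)
        return self.rois[key]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rois]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"label": r.label, "center": list(r.center), "radius": r.radius} for r in self.rois],
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "RoiSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls([RoiSpec(d["label"], tuple(d["center"]), d.get("radius", 5.0)) for d in raw])


#: The 11 published 5 mm seeds (MNI mm).
DEFAULT_ROI_SET = RoiSet(
    [
        RoiSpec("vlPFC_L", (-54.0, 38.0, 3.0)),
        RoiSpec("vlPFC_R", (48.0, 35.0, -2.0)),
        RoiSpec("FPC_R", (15.0, 56.0, 25.0)),
        RoiSpec("putamen_L_A", (-27.0, -19.0, 4.0)),
        RoiSpec("putamen_L_B", (-36.0, -22.0, -8.0)),
        RoiSpec("putamen_R", (33.0, -10.0, 1.0)),
        RoiSpec("SMA_L", (-9.0, 8.0, 55.0)),
        RoiSpec("SMA_R", (9.0, 8.0, 55.0)),
        RoiSpec("caudate_L", (-9.0, 15.0, 3.0)),
        RoiSpec("caudate_R", (9.0, 15.0, 3.0)),
        RoiSpec("OFC", (-3.0, 38.0, -11.0)),
    ]
)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def mm_to_voxel(affine: np.ndarray, mm_coord) -> np.ndarray:
    """Map world (mm) coordinates to continuous 0-based voxel coordinates.

    No rounding is applied; ``mm_coord`` may be a single triplet or an
    ``(n, 3)`` array.
    """
    affine = _check_affine(affine)
    mm = np.atleast_2d(np.asarray(mm_coord, dtype=float))
    homog = np.column_stack([mm, np.ones(len(mm))])
    vox = (np.linalg.inv(affine) @ homog.T).T[:, :3]
    return vox[0] if np.asarray(mm_coord).ndim == 1 else vox


def voxel_to_mm(affine: np.ndarray, vox_coord) -> np.ndarray:
    """Inverse of :func:`mm_to_voxel`."""
    affine = _check_affine(affine)
    vox = np.atleast_2d(np.asarray(vox_coord, dtype=float))
    homog = np.column_stack([vox, np.ones(len(vox))])
    mm = (affine @ homog.T).T[:, :3]
    return mm[0] if np.asarray(vox_coord).ndim == 1 else mm


def sphere_mask(affine: np.ndarray, shape, center_mm, radius_mm: float) -> np.ndarray:
    """Voxel indices whose centers lie within ``radius_mm`` of ``center_mm``.

    Parameters
    ----------
    affine : 4x4 array
        Voxel-to-world transform of the image grid.
    shape : tuple of 3 ints
        Spatial dimensions of the grid; voxels outside are dropped.
    center_mm : (3,) array-like
        Sphere center in world mm.
    radius_mm : float
        Sphere radius in mm (inclusive boundary).

    Returns
    -------
    ndarray of shape (n_voxels, 3), dtype int
        0-based voxel indices; empty (with a warning) if the sphere
        misses the grid entirely.
    """
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    affine = _check_affine(affine)
    shape = tuple(int(s) for s in shape)

    center_vox = mm_to_voxel(affine, np.asarray(center_mm, dtype=float))
    # bounding box in voxel units generous enough for anisotropic/oblique grids
    voxel_size = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    half = np.ceil(radius_mm / voxel_size).astype(int) + 1
    lo = np.floor(center_vox - half).astype(int)
    hi = np.ceil(center_vox + half).astype(int)

    ranges = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    mm = voxel_to_mm(affine, grid.astype(float))
    dist = np.linalg.norm(mm - np.asarray(center_mm, dtype=float), axis=1)
    inside = grid[dist <= radius_mm]
    in_bounds = np.all((inside >= 0) & (inside < np.array(shape)), axis=1)
    inside = inside[in_bounds]
    if len(inside) == 0:
        warnings.warn(
            f"sphere at {tuple(center_mm)} (r={radius_mm} mm) contains no voxels within the grid",
            stacklevel=2,
        )
    return inside


def extract_roi_timeseries(image4d, rois: RoiSet, standardize: bool = True) -> BoldTimeSeries:
    """Per-volume spatial mean over every ROI mask of a 4-D image.

    ``image4d`` is a nibabel spatial image (or a path to one) with time
    on the last axis.  ROI order is preserved.  With ``standardize``
    each ROI series is scaled to zero mean / unit variance before
    modeling; the choice is recorded in the output's ``meta``.
    """
    import nibabel as nib

    if isinstance(image4d, (str,)) or hasattr(image4d, "__fspath__"):
        image4d = nib.load(str(image4d))
    data = np.asanyarray(image4d.dataobj, dtype=np.float32)
    if data.ndim != 4 or data.shape[3] < 1:
        raise ValueError("expected a 4-D image with at least one volume")
    affine = image4d.affine
    tr = float(image4d.header.get_zooms()[3]) if len(image4d.header.get_zooms()) > 3 else 1.0
    if tr <= 0:
        tr = 1.0

    shape = data.shape[:3]
    series = np.empty((data.shape[3], len(rois)))
    mask_sizes: dict[str, int] = {}
    for j, roi in enumerate(rois):
        idx = sphere_mask(affine, shape, roi.center, roi.radius)
        if len(idx) == 0:
            raise ValueError(f"ROI {roi.label!r}: mask is empty within the image grid")
        mask_sizes[roi.label] = len(idx)
        series[:, j] = data[idx[:, 0], idx[:, 1], idx[:, 2], :].mean(axis=0)

    meta = {
        "standardized": bool(standardize),
        "mask_sizes": mask_sizes,
        "affine_digest": hashlib.sha1(np.ascontiguousarray(affine).tobytes()).hexdigest()[:12],
    }
    if standardize:
        series = series - series.mean(axis=0)
        sd = series.std(axis=0)
        sd[sd == 0] = 1.0
        series = series / sd
    return BoldTimeSeries(series, tr=tr, region_labels=rois.labels, meta=meta)
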