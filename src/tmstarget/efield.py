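"""Per-placement E-field weights over gray-matter voxels.

The default is an analytic surrogate field: a Gaussian tangential profile
around the coil center's cortical projection combined with an exponential
decay with depth along the scalp normal, max-normalized and floored to a
sparse support.  Externally simulated field-magnitude volumes (e.g. FEM
output) can be imported through :func:`load_efield_volume` instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .headgeom import GeometryError, HeadModel, ScalpSite, SearchSpace, \
    cpc_to_scalp, project_to_cortex

__all__ = [
    "CoilPlacement",
    "GrayMatterMask",
    "EFieldParams",
    "EFieldWeights",
    "surrogate_efield",
    "load_efield_volume",
    "search_space_fields",
]


@dataclass
class CoilPlacement:
    """A coil position on the scalp with an orientation from the midline."""

    site: ScalpSite
    orientation_deg: float = 45.0
    handle: str = "backward"

    def __post_init__(self) -> None:
        self.orientation_deg = float(self.orientation_deg) % 360.0


@dataclass
class GrayMatterMask:
    """Ordered gray-matter voxel set on a regular grid.

    ``affine`` maps 0-based voxel indices (RAS) to world mm; ``indices`` are
    sorted unique linear (C-order) indices of in-mask voxels, and fix the
    voxel ordering used by every downstream map and time series.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("mask must contain at least one voxel")
        if len(np.unique(idx)) != len(idx) or np.any(np.diff(idx) < 0):
            raise ValueError("mask indices must be sorted and unique")
        self.indices = idx

    @property
    def n_voxels(self) -> int:
        return len(self.indices)

    def voxel_ijk(self) -> np.ndarray:
        return np.column_stack(np.unravel_index(self.indices, self.shape))

    def world_coords(self) -> np.ndarray:
        """World-mm centers of the in-mask voxels, in mask order."""
        ijk = self.voxel_ijk().astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vol = np.full(int(np.prod(self.shape)), fill, dtype=float)
        vol[self.indices] = values
        return vol.reshape(self.shape)

    def to_nifti(self, values: np.ndarray | None = None) -> nib.Nifti1Image:
        data = self.to_volume(np.ones(self.n_voxels) if values is None else values)
        return nib.Nifti1Image(data.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str | Path) -> "GrayMatterMask":
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img))
        data = np.asarray(img.dataobj)
        idx = np.flatnonzero(data > 0)
        return cls(shape=data.shape, affine=np.asarray(img.affine), indices=idx)


@dataclass
class EFieldParams:
    """Surrogate-field shape parameters (mm) and sparsity floor."""

    sigma_mm: float = 10.0
    lambda_mm: float = 20.0
    floor_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0 or self.lambda_mm <= 0:
            raise ValueError("sigma_mm and lambda_mm must be positive")
        if not (0.0 <= self.floor_frac < 1.0):
            raise ValueError("floor_frac must lie in [0, 1)")


@dataclass
class EFieldWeights:
    """Sparse nonnegative per-voxel weights for one coil placement.

    ``support`` holds positions within the mask's voxel ordering; the maximum
    weight is 1 after normalization.
    """

    placement: CoilPlacement
    support: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.support.size == 0:
            raise ValueError("E-field weight support is empty")
        if np.any(self.values < 0):
            raise ValueError("E-field weights must be nonnegative")
        if abs(self.values.max() - 1.0) > 1e-9:
            raise ValueError("E-field weights must be max-normalized to 1")

    def dense(self, n_voxels: int) -> np.ndarray:
        w = np.zeros(n_voxels)
        w[self.support] = self.values
        return w

    def to_nifti(self, mask: GrayMatterMask) -> nib.Nifti1Image:
        return mask.to_nifti(self.dense(mask.n_voxels))

    def to_csv(self, path: str | Path, mask: GrayMatterMask) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["voxel_index", "weight"])
            for pos, w in zip(self.support, self.values):
                writer.writerow([int(mask.indices[pos]), f"{w:.10g}"])


def _normalize_floor(raw: np.ndarray, placement: CoilPlacement,
                     floor_frac: float, meta: dict) -> EFieldWeights:
    m = float(raw.max()) if raw.size else 0.0
    if m <= 0:
        raise GeometryError("E-field is zero over the gray-matter mask")
    w = raw / m
    keep = np.flatnonzero(w >= floor_frac) if floor_frac > 0 else np.flatnonzero(w > 0)
    if keep.size == 0:
        raise GeometryError("E-field support empty after flooring")
    return EFieldWeights(placement=placement, support=keep, values=w[keep], meta=meta)


def surrogate_efield(head: HeadModel, placement: CoilPlacement, mask: GrayMatterMask,
                     params: EFieldParams = EFieldParams()) -> EFieldWeights:
    """Analytic surrogate E-field weights for one coil placement.

    For a voxel at world position x, with c the cortical projection of the
    coil center and n the scalp normal:

        raw(x) = exp(-tang(x)^2 / (2 sigma^2)) * exp(-depth(x) / lambda)

    where ``tang`` is the distance of x from the coil axis (component of
    x - c orthogonal to n) and ``depth`` the scalp-normal distance of x
    beyond c (clamped at 0 above the cortex).  Weights are max-normalized
    and entries below ``floor_frac`` dropped.
    """
    c, used_fallback = project_to_cortex(head, placement.site)
    n = placement.site.normal
    rel = mask.world_coords() - c
    axial = rel @ n
    depth = np.maximum(0.0, -axial)
    tang2 = np.einsum("ij,ij->i", rel, rel) - axial**2
    raw = np.exp(-np.maximum(tang2, 0.0) / (2.0 * params.sigma_mm**2)) \
        * np.exp(-depth / params.lambda_mm)
    meta = {"model": "surrogate", "sigma_mm": params.sigma_mm,
            "lambda_mm": params.lambda_mm, "floor_frac": params.floor_frac,
            "orientation_deg": placement.orientation_deg,
            "cortex_fallback": bool(used_fallback)}
    return _normalize_floor(raw, placement, params.floor_frac, meta)


def load_efield_volume(path: str | Path | nib.Nifti1Image, mask: GrayMatterMask,
                       floor_frac: float = 0.05,
                       placement: CoilPlacement | None = None) -> EFieldWeights:
    """Import an externally simulated field-magnitude volume (NIfTI).

    In-mask magnitudes are sampled with nearest-neighbor interpolation, then
    max-normalized and floored like the surrogate.
    """
    img = path if isinstance(path, nib.spatialimages.SpatialImage) else nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("E-field volume must be a 3-D scalar magnitude image")
    inv = np.linalg.inv(img.affine)
    world = mask.world_coords()
    vox = np.rint(world @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(data.shape)), axis=1)
    if not inside.any():
        raise GeometryError("E-field volume grid does not overlap the mask")
    raw = np.zeros(mask.n_voxels)
    raw[inside] = data[vox[inside, 0], vox[inside, 1], vox[inside, 2]]
    raw = np.maximum(raw, 0.0)
    if raw.max() <= 0:
        raise GeometryError("imported E-field is zero over the gray-matter mask")
    if placement is None:
        placement = CoilPlacement(
            site=ScalpSite(position=np.zeros(3), normal=np.array([0.0, 0.0, 1.0])))
    meta = {"model": "imported", "floor_frac": floor_frac}
    return _normalize_floor(raw, placement, floor_frac, meta)


def search_space_fields(head: HeadModel, mask: GrayMatterMask, space: SearchSpace,
                        params: EFieldParams = EFieldParams(),
                        orientation_deg: float = 45.0
                        ) -> dict[tuple[int, int], EFieldWeights]:
    """Surrogate E-field weights for every included search-space node.

    Geometry (scalp site, cortical projection, weights) depends only on the
    head and grid, so the result can be reused across sessions and durations.
    """
    fields: dict[tuple[int, int], EFieldWeights] = {}
    for i, j, cpc, _ in space.nodes(included_only=True):
        site = cpc_to_scalp(head, cpc)
        placement = CoilPlacement(site=site, orientation_deg=orientation_deg)
        fields[(i, j)] = surrogate_efield(head, placement, mask, params)
    return fields
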