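"""Volume and label-mask I/O with explicit voxel geometry.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)``.
* World coordinates are millimetres, RAS orientation, obtained from the
  4x4 index-to-world affine (NIfTI sform preferred over qform).
* Region masks are integer label grids with a ``legend`` dictionary mapping
  region names (``putamen``, ``globus_pallidus``, ``caudate``,
  ``internal_capsule``, ``parent_artery``) to label ids; background is 0.
* Label resampling is nearest-neighbour: labels are categorical.

Registration to a template is deliberately out of scope: masks arrive either
already aligned to the subject grid or with a user-supplied world-to-world
affine (4x4 whitespace-delimited text file, mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .errors import (
    DimensionalityError,
    GeometryError,
    LegendError,
    SizingError,
    ValidationError,
)

__all__ = [
    "ScalarVolume",
    "RegionLabelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_affine",
    "resample_mask_to_grid",
    "restrict_to_regions",
]


def _spacing_from_affine(affine: np.ndarray) -> Tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class ScalarVolume:
    """A 3D scalar grid with voxel spacing (mm) and index-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = None  # type: ignore[assignment]
    spacing: Tuple[float, float, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if self.affine is None:
            sp = self.spacing if self.spacing is not None else (1.0, 1.0, 1.0)
            self.affine = np.diag([sp[0], sp[1], sp[2], 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if self.spacing is None:
            self.spacing = _spacing_from_affine(self.affine)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxels")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def require_pipeline_size(self, minimum: int = 8) -> None:
        if min(self.shape) < minimum:
            raise SizingError(
                f"grid {self.shape} too small for pipeline use (need >= {minimum} per axis)"
            )

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        """New volume sharing this volume's geometry."""
        return ScalarVolume(np.asarray(data), affine=self.affine.copy(), spacing=self.spacing)


@dataclass
class RegionLabelMask:
    """Integer label grid plus a region-name -> label-id legend (background 0)."""

    labels: np.ndarray
    legend: Dict[str, int]
    affine: np.ndarray = None  # type: ignore[assignment]
    spacing: Tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D label grid, got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValidationError("label grid contains non-integer values")
            self.labels = rounded.astype(np.int32)
        if self.labels.min() < 0:
            raise ValidationError("label grid contains negative labels")
        if self.affine is None:
            sp = self.spacing if self.spacing is not None else (1.0, 1.0, 1.0)
            self.affine = np.diag([sp[0], sp[1], sp[2], 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.spacing is None:
            self.spacing = _spacing_from_affine(self.affine)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.legend = dict(self.legend)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def region_mask(self, names: Iterable[str]) -> np.ndarray:
        """Boolean union of the named regions. Unknown names raise LegendError."""
        names = list(names)
        out = np.zeros(self.labels.shape, dtype=bool)
        for name in names:
            if name not in self.legend:
                known = ", ".join(sorted(self.legend))
                raise LegendError(f"unknown region '{name}'; known regions: {known}")
            out |= self.labels == self.legend[name]
        return out

    def union_mask(self) -> np.ndarray:
        return self.region_mask(self.legend.keys())


def read_volume(path) -> ScalarVolume:
    """Read a 3D NIfTI-1 volume.

    Spacing comes from the header ``pixdim``; the affine is nibabel's
    sform-preferred index-to-world map. Non-3D images and non-finite voxels
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D image, got {data.ndim}D with shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(np.asarray(data, dtype=np.float64), affine=img.affine, spacing=spacing)


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _read_legend(path) -> Dict[str, int]:
    path = Path(path)
    text = path.read_text()
    legend = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(legend, dict):
        raise ValidationError(f"legend file {path} must hold a name->label mapping")
    return {str(k): int(v) for k, v in legend.items()}


def read_mask(path, legend) -> RegionLabelMask:
    """Read a label mask; ``legend`` is a dict or a YAML/JSON sidecar path."""
    vol_path = Path(path)
    if not vol_path.exists():
        raise FileNotFoundError(f"no such mask file: {vol_path}")
    img = nib.load(str(vol_path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise DimensionalityError(f"{vol_path.name}: mask must be 3D, got {labels.ndim}D")
    if not isinstance(legend, Mapping):
        legend = _read_legend(legend)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RegionLabelMask(labels, dict(legend), affine=img.affine, spacing=spacing)


def write_mask(mask: RegionLabelMask, path, legend_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    if legend_path is not None:
        Path(legend_path).write_text(yaml.safe_dump(dict(mask.legend)))


def read_affine(path) -> np.ndarray:
    """Read a 4x4 world-to-world affine from whitespace-delimited text (mm)."""
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise GeometryError(f"affine file {path} must be 4x4, got {mat.shape}")
    return mat


def resample_mask_to_grid(
    mask: RegionLabelMask, transform: np.ndarray, target: ScalarVolume
) -> RegionLabelMask:
    """Nearest-neighbour resample of a label mask onto the target grid.

    ``transform`` is a world-to-world affine (mm) mapping mask world
    coordinates into target world coordinates. The full chain for a target
    voxel index ``i`` is::

        mask_index = A_mask^-1 . T^-1 . A_target . i

    Labels are categorical, so only order-0 interpolation is used; the
    output legend is the input legend unchanged.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise GeometryError(f"transform must be 4x4, got {transform.shape}")
    try:
        t_inv = np.linalg.inv(transform)
        m_inv = np.linalg.inv(mask.affine)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular transform: {exc}") from exc
    chain = m_inv @ t_inv @ target.affine
    out = ndimage.affine_transform(
        mask.labels,
        matrix=chain[:3, :3],
        offset=chain[:3, 3],
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
        output=mask.labels.dtype,
    )
    return RegionLabelMask(out, dict(mask.legend), affine=target.affine.copy(), spacing=target.spacing)


def restrict_to_regions(
    volume: ScalarVolume, mask: RegionLabelMask, region_names: Sequence[str]
) -> ScalarVolume:
    """Zero every voxel outside the union of the named regions.

    In-mask voxels are unchanged, so the operation is idempotent.
    """
    if mask.shape != volume.shape:
        raise GeometryError(
            f"mask grid {mask.shape} does not match volume grid {volume.shape}"
        )
    keep = mask.region_mask(region_names)
    out = np.where(keep, volume.data, 0)
    return volume.with_data(out)
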