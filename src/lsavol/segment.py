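"""Threshold selection, vessel extraction, volumetry and QC.

The binarization threshold is chosen by a volume-ratio scheme: candidate
thresholds descend through the in-ROI intensity range, and at each step the
vessel-to-tissue volume ratio (suprathreshold voxels / total ROI voxels, in
percent) is recomputed. While the candidate sits above the parenchyma
intensities the ratio barely moves; the first step whose ratio change
exceeds the stopping constant (default 0.2 percentage points) marks
parenchyma onset, and the previous candidate is returned. The full sweep
curves are kept for audit.

Vascular volume is the suprathreshold voxel count multiplied by the voxel
volume (the product of the three voxel edge lengths).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    GeometryError,
    SeedError,
    SelectionError,
)
from .image_io import RegionLabelMask, ScalarVolume

__all__ = [
    "ThresholdSelection",
    "RegionVolumeReport",
    "LargeVesselQC",
    "vascular_volume_mm3",
    "select_threshold",
    "extract_vessels",
    "quantify_region_volumes",
    "flag_large_vessels",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def vascular_volume_mm3(n_voxels: float, spacing: Sequence[float]) -> float:
    """Vascular volume: voxel count x voxel volume (sx*sy*sz, mm^3)."""
    sx, sy, sz = spacing
    return float(n_voxels) * sx * sy * sz


@dataclass
class ThresholdSelection:
    """Audit record of one volume-ratio threshold sweep.

    ``candidate_thresholds`` descend from the in-ROI maximum; ``volume_curve``
    is the suprathreshold in-ROI voxel count per candidate,
    ``ratio_change_curve`` the per-step change of the vessel-to-ROI volume
    ratio in percentage points. ``selected_step_index`` is the step whose
    change first exceeded the stopping constant.
    """

    candidate_thresholds: np.ndarray
    volume_curve: np.ndarray
    ratio_curve: np.ndarray
    ratio_change_curve: np.ndarray
    selected_threshold: float
    selected_step_index: int
    delta_star: float
    step_percentile: float

    def __post_init__(self):
        c = np.asarray(self.candidate_thresholds, dtype=float)
        v = np.asarray(self.volume_curve)
        if np.any(np.diff(c) > 0):
            raise ValueError("candidate thresholds must be descending")
        if np.any(np.diff(v) < 0):
            raise ValueError("volume curve must be non-decreasing along the walk")
        if np.any(np.asarray(self.ratio_change_curve) < -1e-9):
            raise ValueError("ratio changes must be non-negative")
        if not np.any(np.isclose(c, self.selected_threshold)):
            raise ValueError("selected threshold must be one of the candidates")

    def to_dict(self) -> dict:
        return {
            "selected_threshold": float(self.selected_threshold),
            "selected_step_index": int(self.selected_step_index),
            "delta_star": float(self.delta_star),
            "step_percentile": float(self.step_percentile),
            "candidate_thresholds": np.asarray(self.candidate_thresholds).tolist(),
            "volume_curve": np.asarray(self.volume_curve).tolist(),
            "ratio_curve": np.asarray(self.ratio_curve).tolist(),
            "ratio_change_curve": np.asarray(self.ratio_change_curve).tolist(),
        }


def select_threshold(
    enhanced: ScalarVolume,
    roi: RegionLabelMask,
    region_names: Optional[Sequence[str]] = None,
    step_percentile: float = 0.5,
    delta_star: float = 0.2,
) -> ThresholdSelection:
    """Walk candidate thresholds downward until parenchyma onset.

    Candidates step down from the in-ROI maximum in increments of
    ``step_percentile`` percent of the in-ROI intensity range; selection is
    invariant under affine intensity rescaling. The walk stops at the first
    step whose vessel-to-ROI ratio change exceeds ``delta_star`` percentage
    points and returns the previous candidate.
    """
    if not (0 < step_percentile <= 5):
        raise ValueError("step_percentile must lie in (0, 5]")
    if delta_star <= 0:
        raise ValueError("delta_star must be > 0")
    if roi.shape != enhanced.shape:
        raise GeometryError(f"ROI grid {roi.shape} != volume grid {enhanced.shape}")

    roi_mask = roi.union_mask() if region_names is None else roi.region_mask(region_names)
    vals = enhanced.data[roi_mask]
    if vals.size == 0:
        raise DegenerateInputError("ROI is empty")
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo <= 0:
        raise DegenerateInputError("ROI intensities are constant; no threshold exists")

    n_steps = int(np.ceil(100.0 / step_percentile))
    ks = np.arange(0, n_steps + 1)
    candidates = hi - ks * (step_percentile / 100.0) * (hi - lo)
    candidates[-1] = lo

    n_roi = vals.size
    counts = np.array([(vals >= t).sum() for t in candidates], dtype=np.int64)
    ratios = 100.0 * counts / n_roi
    changes = np.diff(ratios)  # change at step k = ratios[k] - ratios[k-1], k >= 1

    exceed = np.nonzero(changes > delta_star)[0]
    if exceed.size == 0:
        raise SelectionError(
            f"no step changed the volume ratio by more than {delta_star}%; "
            "try a smaller step_percentile"
        )
    stop = int(exceed[0]) + 1  # index into candidates of the offending step
    # Return the candidate one step above the previous candidate: the step
    # straddling the parenchyma mode edge can pick up sub-delta-star mass
    # through grid quantization, so a one-step guard band keeps the selected
    # threshold clear of the onset.
    sel = max(stop - 2, 0)
    return ThresholdSelection(
        candidate_thresholds=candidates,
        volume_curve=counts,
        ratio_curve=ratios,
        ratio_change_curve=np.concatenate([[0.0], changes]),
        selected_threshold=float(candidates[sel]),
        selected_step_index=stop,
        delta_star=delta_star,
        step_percentile=step_percentile,
    )


def _seed_component(labels: np.ndarray, mask: np.ndarray, seed: Tuple[int, int, int]) -> int:
    """Component id containing (or nearest within 5 voxels of) the seed."""
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, mask.shape)):
        raise SeedError(f"seed {seed} outside grid {mask.shape}")
    if mask[seed]:
        return int(labels[seed])
    warnings.warn(
        f"seed {seed} is below threshold; using nearest suprathreshold voxel",
        stacklevel=3,
    )
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise SeedError("no suprathreshold voxel anywhere in the ROI")
    d2 = ((idx - np.asarray(seed)) ** 2).sum(axis=1)
    j = int(np.argmin(d2))
    if d2[j] > 25:
        raise SeedError(f"no suprathreshold voxel within 5 voxels of seed {seed}")
    return int(labels[tuple(idx[j])])


def extract_vessels(
    enhanced: ScalarVolume,
    selection: ThresholdSelection,
    roi: RegionLabelMask,
    seed: Optional[Tuple[int, int, int]] = None,
    region_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Binary vessel mask: in-ROI voxels at or above the selected threshold.

    With a seed voxel, only 26-connected components belonging to the seed's
    vessel tree are kept: the seed's own component plus any component whose
    1-voxel dilation touches it. Without a seed all suprathreshold voxels
    are kept (fully automatic batch mode).
    """
    if roi.shape != enhanced.shape:
        raise GeometryError(f"ROI grid {roi.shape} != volume grid {enhanced.shape}")
    roi_mask = roi.union_mask() if region_names is None else roi.region_mask(region_names)
    mask = (enhanced.data >= selection.selected_threshold) & roi_mask
    if seed is None or not mask.any():
        return mask

    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    seed_id = _seed_component(labels, mask, seed)
    seed_comp = labels == seed_id
    touching = ndimage.binary_dilation(seed_comp, structure=_STRUCT_26)
    keep_ids = np.unique(labels[touching & mask])
    keep_ids = keep_ids[keep_ids > 0]
    return np.isin(labels, keep_ids)


@dataclass
class RegionVolumeReport:
    """Per-region vessel voxel counts and volumes.

    ``volume = count * voxel_volume`` holds exactly for every row; fractions
    are over the total vessel voxels in the ROI union and are ``None``
    (flagged undefined) when the vessel set is empty.
    """

    per_region: Dict[str, dict]
    total_voxel_count: int
    total_volume_mm3: float
    voxel_volume_mm3: float
    fractions_defined: bool = True

    def __post_init__(self):
        for name, row in self.per_region.items():
            expect = vascular_volume_mm3(row["voxels"], (self.voxel_volume_mm3, 1.0, 1.0))
            assert row["volume_mm3"] == expect, f"volume arithmetic broken for {name}"
        assert self.total_volume_mm3 == vascular_volume_mm3(
            self.total_voxel_count, (self.voxel_volume_mm3, 1.0, 1.0)
        )

    def to_dict(self) -> dict:
        return {
            "per_region": self.per_region,
            "total_voxel_count": int(self.total_voxel_count),
            "total_volume_mm3": float(self.total_volume_mm3),
            "voxel_volume_mm3": float(self.voxel_volume_mm3),
            "fractions_defined": bool(self.fractions_defined),
        }


def quantify_region_volumes(
    vessel_mask: np.ndarray,
    roi: RegionLabelMask,
    spacing: Sequence[float],
) -> RegionVolumeReport:
    """Count vessel voxels per region and convert to mm^3.

    The total is taken over the union of all legend regions; fractions are
    each region's share of that total (undefined-flagged if it is zero).
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != roi.shape:
        raise GeometryError(
            f"vessel mask grid {vessel_mask.shape} != ROI grid {roi.shape}"
        )
    if not np.allclose(spacing, roi.spacing, rtol=1e-6):
        raise GeometryError(
            f"spacing mismatch: vessel carrier {tuple(spacing)} vs ROI {roi.spacing}"
        )
    vv = float(np.prod(np.asarray(spacing, dtype=float)))
    total = int((vessel_mask & roi.union_mask()).sum())
    defined = total > 0
    per_region = {}
    for name in roi.legend:
        count = int((vessel_mask & roi.region_mask([name])).sum())
        per_region[name] = {
            "voxels": count,
            "volume_mm3": vascular_volume_mm3(count, (vv, 1.0, 1.0)),
            "fraction_of_total_vessel": (count / total) if defined else None,
        }
    return RegionVolumeReport(
        per_region=per_region,
        total_voxel_count=total,
        total_volume_mm3=vascular_volume_mm3(total, (vv, 1.0, 1.0)),
        voxel_volume_mm3=vv,
        fractions_defined=defined,
    )


@dataclass
class LargeVesselQC:
    """Result of the large-artery contamination check."""

    passed: bool
    flagged_components: List[dict] = field(default_factory=list)
    radius_limit_mm: float = 0.0

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "radius_limit_mm": float(self.radius_limit_mm),
            "flagged_components": self.flagged_components,
        }


def flag_large_vessels(
    vessel_mask: np.ndarray,
    spacing: Sequence[float],
    d_max: float = 5.0,
) -> LargeVesselQC:
    """Flag connected components thicker than the targeted vessel calibre.

    The maximum inscribed radius of each 26-connected component is read off
    the Euclidean distance transform (mm); components exceeding
    ``d_max / 2`` voxels (converted to mm via the mean voxel edge) indicate
    large-artery contamination of the ROI, the exclusion criterion used for
    whole cases. An empty mask passes vacuously.
    """
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    limit_mm = (d_max / 2.0) * float(np.mean(spacing))
    if not vessel_mask.any():
        return LargeVesselQC(passed=True, radius_limit_mm=limit_mm)
    edt = ndimage.distance_transform_edt(vessel_mask, sampling=spacing)
    labels, n = ndimage.label(vessel_mask, structure=_STRUCT_26)
    max_r = ndimage.maximum(edt, labels=labels, index=np.arange(1, n + 1))
    max_r = np.atleast_1d(max_r)
    flagged = [
        {"component_id": int(i + 1), "max_inscribed_radius_mm": float(r)}
        for i, r in enumerate(max_r)
        if r > limit_mm
    ]
    return LargeVesselQC(passed=not flagged, flagged_components=flagged, radius_limit_mm=limit_mm)
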