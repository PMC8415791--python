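"""Synthetic TOF-like angiogram phantoms with known ground truth.

The generator emulates the imaging situation the pipeline targets: bright,
thin, branching perforator-like vessels (diameters of roughly 1-5 voxels)
rising from a parent artery into darker parenchyma, with a smooth
multiplicative bias field (dielectric shading at ultra-high field) and
Rician magnitude noise. Ellipsoidal stand-ins for the putamen, globus
pallidus, caudate nucleus and posterior limb of the internal capsule provide
subcortical region masks; the standard tree is positioned so that it crosses
the putamen-like region predominantly.

Ground truth is geometric and defined *before* noise: a voxel belongs to the
true vessel mask iff its centre lies within the local tube radius of the
centerline. That makes the phantom an unambiguous oracle for volume-recovery
and topology-recovery tests.

All randomness flows from explicit integer seeds; equal seeds give
bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import SizingError
from .image_io import RegionLabelMask, ScalarVolume, write_mask, write_volume

__all__ = [
    "VesselTreeSpec",
    "Segment",
    "PhantomTruth",
    "generate_vessel_tree",
    "render_angiogram",
    "generate_region_masks",
    "make_phantom_case",
    "write_phantom_case",
]

REGION_LABELS = {
    "putamen": 1,
    "globus_pallidus": 2,
    "caudate": 3,
    "internal_capsule": 4,
}
PARENT_ARTERY_LABEL = 5


@dataclass
class VesselTreeSpec:
    """Parameters of a recursive binary vessel tree.

    Lengths and positions are in mm. ``curvature_deg_per_mm`` bounds the
    per-step bend of each centerline polyline; ``radius_ratio`` is the
    child/parent radius factor (children never wider than the parent).
    """

    root_position_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    root_direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    root_radius_mm: float = 0.6
    n_generations: int = 2
    branching_angle_deg: Tuple[float, float] = (20.0, 45.0)
    segment_length_mm: Tuple[float, float] = (8.0, 14.0)
    radius_ratio: float = 0.8
    curvature_deg_per_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.root_radius_mm <= 0:
            raise ValueError("root_radius_mm must be > 0")
        if not (0 < self.radius_ratio <= 1):
            raise ValueError("radius_ratio must lie in (0, 1]")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")


@dataclass
class Segment:
    """One centerline segment: a polyline in mm with a constant tube radius."""

    segment_id: int
    parent_id: Optional[int]
    points_mm: np.ndarray  # (N, 3)
    radius_mm: float
    generation: int


@dataclass
class PhantomTruth:
    """Ground truth of one rendered phantom."""

    vessel_mask: np.ndarray  # bool grid
    tree: List[Segment]
    region_mask: Optional[RegionLabelMask]
    per_region_true_volume_mm3: Dict[str, float]
    params: dict
    noise_sigma: float
    bias_amplitude: float
    bias_field: Optional[np.ndarray] = None

    def true_volume_mm3(self, spacing: Sequence[float]) -> float:
        return float(self.vessel_mask.sum()) * float(np.prod(spacing))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, v)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, a))


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _grow_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    curvature_deg_per_mm: float,
    rng: np.random.Generator,
    step_mm: float = 0.5,
    bounds_mm: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Random-walk a smooth polyline; per-step bend <= curvature * step.

    Returns (points, final direction, truncated-at-bounds flag).
    """
    n_steps = max(2, int(round(length / step_mm)))
    pts = [start.copy()]
    d = _unit(direction.astype(float))
    truncated = False
    max_bend = np.deg2rad(curvature_deg_per_mm) * step_mm
    for _ in range(n_steps):
        bend = rng.uniform(0, max_bend)
        azimuth = rng.uniform(0, 2 * np.pi)
        axis = _rotate_about(_perpendicular(d), d, azimuth)
        d = _unit(_rotate_about(d, axis, bend))
        nxt = pts[-1] + d * step_mm
        if bounds_mm is not None and (np.any(nxt < bounds_mm[0]) or np.any(nxt > bounds_mm[1])):
            truncated = True
            break
        pts.append(nxt)
    return np.array(pts), d, truncated


def generate_vessel_tree(
    spec: VesselTreeSpec, bounds_mm: Optional[Sequence[Sequence[float]]] = None
) -> List[Segment]:
    """Grow a binary branching centerline tree, deterministic given the seed.

    ``n_generations = 0`` yields a single unbranched trunk; a full binary
    tree of g generations has ``2**(g+1) - 1`` segments. If a segment would
    leave ``bounds_mm`` (``[[x0,y0,z0],[x1,y1,z1]]``) it is truncated with a
    warning; growth never continues silently outside the box.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = np.asarray(bounds_mm, dtype=float) if bounds_mm is not None else None
    segments: List[Segment] = []
    next_id = [0]

    def grow(start, direction, radius, generation, parent_id):
        length = rng.uniform(*spec.segment_length_mm)
        pts, d_end, truncated = _grow_polyline(
            start, direction, length, spec.curvature_deg_per_mm, rng, bounds_mm=bounds
        )
        if truncated:
            warnings.warn(
                "vessel tree truncated at bounding box; a segment was cut short",
                stacklevel=2,
            )
            if len(pts) < 3:
                return  # degenerate stub: drop it entirely rather than keep a point
        seg = Segment(next_id[0], parent_id, pts, radius, generation)
        next_id[0] += 1
        segments.append(seg)
        if generation < spec.n_generations and not truncated:
            angle = np.deg2rad(rng.uniform(*spec.branching_angle_deg))
            azimuth = rng.uniform(0, 2 * np.pi)
            axis = _rotate_about(_perpendicular(d_end), d_end, azimuth)
            d1 = _unit(_rotate_about(d_end, axis, angle / 2))
            d2 = _unit(_rotate_about(d_end, axis, -angle / 2))
            child_r = radius * spec.radius_ratio
            for d_child in (d1, d2):
                grow(pts[-1].copy(), d_child, child_r, generation + 1, seg.segment_id)

    grow(
        np.asarray(spec.root_position_mm, dtype=float),
        np.asarray(spec.root_direction, dtype=float),
        spec.root_radius_mm,
        0,
        None,
    )
    return segments


def _signed_distance_field(
    tree: Sequence[Segment], shape, spacing, pad_mm: float
) -> np.ndarray:
    """Min over the tree of (distance to centerline - local radius), in mm.

    Computed by dense sampling of each polyline and local box updates; the
    sampling step is a quarter of the finest voxel edge so the discretization
    error is well below half a voxel.
    """
    spacing = np.asarray(spacing, dtype=float)
    sdf = np.full(shape, np.inf, dtype=np.float32)
    step = float(spacing.min()) / 4.0
    for seg in tree:
        pts = seg.points_mm
        # resample polyline densely
        deltas = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(deltas)])
        total = arclen[-1]
        if total == 0:
            samples = pts[:1]
        else:
            s = np.arange(0, total + step, step)
            samples = np.column_stack(
                [np.interp(s, arclen, pts[:, ax]) for ax in range(3)]
            )
        reach = seg.radius_mm + pad_mm
        half = np.ceil(reach / spacing).astype(int) + 1
        for p in samples:
            c = p / spacing  # voxel coordinates of the sample
            lo = np.maximum(np.floor(c).astype(int) - half, 0)
            hi = np.minimum(np.floor(c).astype(int) + half + 1, shape)
            if np.any(lo >= hi):
                continue
            ii, jj, kk = np.meshgrid(
                np.arange(lo[0], hi[0]),
                np.arange(lo[1], hi[1]),
                np.arange(lo[2], hi[2]),
                indexing="ij",
            )
            d = np.sqrt(
                ((ii * spacing[0]) - p[0]) ** 2
                + ((jj * spacing[1]) - p[1]) ** 2
                + ((kk * spacing[2]) - p[2]) ** 2
            ).astype(np.float32)
            region = sdf[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            np.minimum(region, d - seg.radius_mm, out=region)
    return sdf


def _bias_field(shape, spacing, amplitude: float, smoothness_mm: float, rng) -> np.ndarray:
    """Heavily smoothed white noise rescaled to [1 - a, 1 + a]."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    noise = rng.standard_normal(shape).astype(np.float32)
    sig = [smoothness_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sig)
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        return np.ones(shape, dtype=np.float32)
    return (1.0 - amplitude) + 2.0 * amplitude * (smooth - lo) / (hi - lo)


def render_angiogram(
    tree: Sequence[Segment],
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    vessel_intensity: float = 200.0,
    background_intensity: float = 40.0,
    edge_softness_mm: float = 0.3,
    bias_amplitude: float = 0.0,
    bias_smoothness_mm: float = 20.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "rician",
    region_mask: Optional[RegionLabelMask] = None,
) -> Tuple[ScalarVolume, PhantomTruth]:
    """Render a centerline tree into a TOF-like intensity volume.

    Voxels within the tube radius get ``vessel_intensity`` with a smooth
    falloff of width ``edge_softness_mm`` at the wall; the rest is
    ``background_intensity``. A multiplicative bias field in
    ``[1-a, 1+a]`` is applied, then Rician (default) or Gaussian noise.

    The returned :class:`PhantomTruth` carries the pre-noise geometric
    vessel mask (voxel centre inside the tube), the bias field, and
    per-region true volumes when a region mask is supplied.
    """
    if not vessel_intensity > background_intensity >= 0:
        raise ValueError("require vessel_intensity > background_intensity >= 0")
    spacing = tuple(float(s) for s in spacing)
    min_r = min(seg.radius_mm for seg in tree)
    if min_r < 0.5 * min(spacing):
        warnings.warn(
            f"sub-voxel vessel: radius {min_r:.3g} mm < half the finest voxel edge",
            stacklevel=2,
        )
    sdf = _signed_distance_field(tree, shape, spacing, pad_mm=edge_softness_mm)
    vessel_mask = sdf <= 0.0

    if edge_softness_mm > 0:
        t = np.clip(sdf / edge_softness_mm, 0.0, 1.0)
        falloff = 0.5 * (1 + np.cos(np.pi * t))  # smooth wall profile
    else:
        falloff = vessel_mask.astype(np.float32)
    img = background_intensity + (vessel_intensity - background_intensity) * falloff

    rng = np.random.default_rng(seed)
    bias = _bias_field(shape, spacing, bias_amplitude, bias_smoothness_mm, rng)
    img = img * bias

    if noise_sigma > 0:
        if noise_model == "rician":
            n1 = rng.standard_normal(shape) * noise_sigma
            n2 = rng.standard_normal(shape) * noise_sigma
            img = np.sqrt((img + n1) ** 2 + n2**2)
        elif noise_model == "gaussian":
            img = img + rng.standard_normal(shape) * noise_sigma
        else:
            raise ValueError(f"unknown noise model '{noise_model}'")

    volume = ScalarVolume(np.asarray(img, dtype=np.float64), spacing=spacing)
    per_region = {}
    if region_mask is not None:
        vv = float(np.prod(spacing))
        for name in region_mask.legend:
            per_region[name] = float(
                np.logical_and(vessel_mask, region_mask.region_mask([name])).sum()
            ) * vv
    truth = PhantomTruth(
        vessel_mask=vessel_mask,
        tree=list(tree),
        region_mask=region_mask,
        per_region_true_volume_mm3=per_region,
        params={
            "vessel_intensity": vessel_intensity,
            "background_intensity": background_intensity,
            "edge_softness_mm": edge_softness_mm,
            "bias_smoothness_mm": bias_smoothness_mm,
            "noise_model": noise_model,
            "seed": seed,
        },
        noise_sigma=noise_sigma,
        bias_amplitude=bias_amplitude,
        bias_field=bias,
    )
    return volume, truth


def _ellipsoid(shape, spacing, center_frac, semiaxes_frac) -> np.ndarray:
    """Boolean ellipsoid; center and semiaxes as fractions of the grid extent."""
    shape = np.asarray(shape)
    extent = shape * np.asarray(spacing)
    center = np.asarray(center_frac) * extent
    semi = np.asarray(semiaxes_frac) * extent
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return q <= 1.0


def generate_region_masks(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    layout_seed: int = 0,
) -> RegionLabelMask:
    """Four pairwise-disjoint subcortical-like regions.

    Ellipsoids stand in for the putamen (label 1, large, central — the
    standard phantom tree runs through it), globus pallidus (2, medial to
    the putamen), caudate (3, superior-medial) and the posterior limb of the
    internal capsule (4, a thin slab between putamen and globus pallidus).
    The layout jitters slightly with ``layout_seed``; identical seeds give
    identical masks. Earlier labels take priority, so regions are disjoint
    by construction.
    """
    if min(shape) < 24:
        raise SizingError(f"grid {shape} too small for the region layout (need >= 24 per axis)")
    rng = np.random.default_rng(layout_seed)
    jitter = lambda: rng.uniform(-0.01, 0.01, size=3)  # noqa: E731

    layout = {
        "putamen": ((0.50, 0.42, 0.45), (0.20, 0.14, 0.30)),
        "globus_pallidus": ((0.50, 0.70, 0.38), (0.12, 0.09, 0.14)),
        "caudate": ((0.50, 0.74, 0.72), (0.13, 0.10, 0.16)),
        "internal_capsule": ((0.50, 0.58, 0.62), (0.10, 0.045, 0.13)),
    }
    labels = np.zeros(shape, dtype=np.int16)
    for name, (c, a) in layout.items():
        ell = _ellipsoid(shape, spacing, np.asarray(c) + jitter(), a)
        labels[(labels == 0) & ell] = REGION_LABELS[name]
    return RegionLabelMask(labels, dict(REGION_LABELS), spacing=spacing)


def make_phantom_case(
    seed: int = 0,
    shape: Tuple[int, int, int] = (96, 96, 96),
    spacing: Tuple[float, float, float] = (0.4, 0.4, 0.4),
    n_generations: int = 2,
    root_radius_mm: float = 0.6,
    vessel_intensity: float = 200.0,
    background_intensity: float = 40.0,
    noise_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
    parent_artery: bool = True,
    parent_radius_mm: float = 1.0,
) -> Tuple[ScalarVolume, PhantomTruth]:
    """The standard phantom: a parent artery near the grid base with a
    perforator tree rising through the putamen-like region.

    The parent artery runs horizontally (a proxy for an M1 segment); the
    tree root sits on it and grows superiorly. The region mask gains a
    ``parent_artery`` legend entry (label 5) covering a capsule around the
    parent vessel, which the morphometry stage uses for rooting.
    """
    extent = np.asarray(shape) * np.asarray(spacing)
    region = generate_region_masks(shape, spacing, layout_seed=seed)

    root = np.array([0.50, 0.42, 0.18]) * extent
    spec = VesselTreeSpec(
        root_position_mm=tuple(root),
        root_direction=(0.0, 0.0, 1.0),
        root_radius_mm=root_radius_mm,
        n_generations=n_generations,
        segment_length_mm=(0.18 * extent[2], 0.24 * extent[2]),
        seed=seed,
    )
    margin = 2 * max(spacing)
    bounds = [[margin] * 3, list(extent - margin)]
    tree = list(generate_vessel_tree(spec, bounds_mm=bounds))

    parent_seg = None
    if parent_artery:
        # straight M1-like tube through the tree root, along x
        y0, z0 = root[1], root[2]
        pts = np.array(
            [[0.12 * extent[0], y0, z0], [0.88 * extent[0], y0, z0]]
        )
        parent_seg = Segment(-1, None, pts, parent_radius_mm, -1)
        tree = [parent_seg] + tree

    legend = dict(REGION_LABELS)
    labels = region.labels.copy()
    if parent_artery:
        sdf_parent = _signed_distance_field([parent_seg], shape, spacing, pad_mm=1.0)
        capsule = sdf_parent <= 1.0  # parent tube + 1 mm margin
        labels[capsule] = PARENT_ARTERY_LABEL
        legend["parent_artery"] = PARENT_ARTERY_LABEL
    region = RegionLabelMask(labels, legend, affine=region.affine, spacing=spacing)

    volume, truth = render_angiogram(
        tree,
        shape,
        spacing,
        vessel_intensity=vessel_intensity,
        background_intensity=background_intensity,
        noise_sigma=noise_sigma,
        bias_amplitude=bias_amplitude,
        seed=seed,
        region_mask=region,
    )
    truth.params["tree_spec"] = asdict(spec)
    return volume, truth


def write_phantom_case(volume: ScalarVolume, truth: PhantomTruth, out_dir) -> None:
    """Export a phantom case: NIfTI volume, truth mask, region mask + legend,
    and a JSON truth record (tree polylines, volumes, parameters)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(volume, out / "angiogram.nii.gz")
    write_volume(
        volume.with_data(truth.vessel_mask.astype(np.uint8)), out / "true_vessels.nii.gz"
    )
    if truth.region_mask is not None:
        write_mask(truth.region_mask, out / "regions.nii.gz", out / "legend.yaml")
    record = {
        "per_region_true_volume_mm3": truth.per_region_true_volume_mm3,
        "true_volume_mm3": truth.true_volume_mm3(volume.spacing),
        "noise_sigma": truth.noise_sigma,
        "bias_amplitude": truth.bias_amplitude,
        "params": truth.params,
        "tree": [
            {
                "id": s.segment_id,
                "parent": s.parent_id,
                "radius_mm": s.radius_mm,
                "generation": s.generation,
                "points_mm": np.asarray(s.points_mm).tolist(),
            }
            for s in truth.tree
        ],
    }
    (out / "truth.json").write_text(
        json.dumps(record, indent=1, sort_keys=True, default=float)
    )
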