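"""Self-validation benchmarks on synthetic phantoms.

Each routine builds its own seeded phantom inputs, runs the regular package
code paths on them, and returns measured quantities — volume-recovery error
through the full enhancement/threshold/quantification chain, skeleton
topology recovery, threshold-scheme audits, agreement-statistic checks, and
bit-level determinism of the case pipeline. ``scripts/acceptance.py`` and
the acceptance test suite both run these.
"""

from __future__ import annotations

import hashlib
import tempfile
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np

from .enhance import VesselnessParams, correct_bias, vesselness
from .image_io import RegionLabelMask, ScalarVolume
from .morpho import count_stems_branches, skeletonize_to_graph
from .pipeline import CaseConfig, run_case
from .segment import extract_vessels, quantify_region_volumes, select_threshold
from .stats import icc_agreement
from .synth import (
    Segment,
    VesselTreeSpec,
    generate_vessel_tree,
    make_phantom_case,
    render_angiogram,
    write_phantom_case,
)

__all__ = [
    "cylinder_volume_recovery",
    "topology_recovery",
    "threshold_gap_audit",
    "icc_validation",
    "determinism_check",
]


def _oblique_cylinder(diameter_vox, shape, spacing, seed=0):
    """Hard-edged cylinder in generic (oblique, off-lattice) position."""
    r = diameter_vox / 2.0 * min(spacing)
    extent = np.asarray(shape) * np.asarray(spacing)
    rng = np.random.default_rng(seed)
    p0 = (np.array([0.25, 0.28, 0.12]) + rng.uniform(-0.02, 0.02, 3)) * extent
    p1 = (np.array([0.60, 0.52, 0.88]) + rng.uniform(-0.02, 0.02, 3)) * extent
    seg = Segment(0, None, np.array([p0, p1]), r, 0)
    vol, truth = render_angiogram(
        [seg],
        shape,
        spacing,
        vessel_intensity=200.0,
        background_intensity=40.0,
        edge_softness_mm=0.0,
        noise_sigma=0.0,
    )
    analytic = np.pi * r * r * float(np.linalg.norm(p1 - p0))
    return vol, truth, analytic


def cylinder_volume_recovery(
    seed: int = 0,
    shape: Tuple[int, int, int] = (96, 96, 96),
    spacing: Tuple[float, float, float] = (0.4, 0.4, 0.4),
    diameters_vox: Sequence[int] = (2, 3, 4, 5),
) -> Dict:
    """Noiseless cylinders through bias-correction, vesselness, volume-ratio
    thresholding and volumetry; error vs the analytic pi*r^2*L volume."""
    errors = {}
    roi = RegionLabelMask(
        np.ones(shape, dtype=np.int16), {"roi": 1}, spacing=spacing
    )
    for d in diameters_vox:
        vol, truth, analytic = _oblique_cylinder(d, shape, spacing, seed=seed + d)
        corrected, _ = correct_bias(vol)
        enhanced = vesselness(corrected, VesselnessParams())
        selection = select_threshold(enhanced, roi)
        mask = extract_vessels(enhanced, selection, roi)
        report = quantify_region_volumes(mask, roi, spacing)
        errors[int(d)] = 100.0 * (report.total_volume_mm3 - analytic) / analytic
    max_abs = max(abs(e) for e in errors.values())
    return {"per_diameter_error_pct": errors, "max_abs_error_pct": max_abs}


def _phantom_tree_case(seed: int, shape, spacing):
    extent = np.asarray(shape) * np.asarray(spacing)
    spec = VesselTreeSpec(
        root_position_mm=(0.5 * extent[0], 0.5 * extent[1], 3.2),
        root_direction=(0.0, 0.0, 1.0),
        root_radius_mm=0.7,
        n_generations=1 + seed % 2,
        branching_angle_deg=(35.0, 60.0),
        segment_length_mm=(6.5, 8.5),
        radius_ratio=0.85,
        curvature_deg_per_mm=3.0,
        seed=seed,
    )
    margin = 3 * max(spacing)
    tree = generate_vessel_tree(spec, bounds_mm=[[margin] * 3, list(extent - margin)])
    leaves = [
        s for s in tree if not any(c.parent_id == s.segment_id for c in tree)
    ]
    _, truth = render_angiogram(
        tree, shape, spacing, vessel_intensity=100.0, background_intensity=0.0
    )
    parent = np.zeros(shape, dtype=bool)
    c = np.round(np.asarray(spec.root_position_mm) / np.asarray(spacing)).astype(int)
    parent[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = True
    return truth, parent, (1, len(leaves))


def topology_recovery(
    seed: int = 0,
    n_trees: int = 20,
    shape: Tuple[int, int, int] = (64, 64, 64),
    spacing: Tuple[float, float, float] = (0.4, 0.4, 0.4),
) -> Dict:
    """Stem/branch counts from skeleton morphometry vs generating topology,
    over seeded binary trees with tube diameters >= 2 voxels, plus the
    trunk-without-branches convention (counts as one stem and one branch)."""
    matches = 0
    mismatches = []
    for k in range(n_trees):
        truth, parent, expected = _phantom_tree_case(seed + k, shape, spacing)
        skel = skeletonize_to_graph(truth.vessel_mask, spacing, parent_mask=parent)
        got = count_stems_branches(skel)
        if got == expected:
            matches += 1
        else:
            mismatches.append({"seed": seed + k, "expected": expected, "got": got})

    # unbranched trunk: recorded as both one stem and one branch
    extent = np.asarray(shape) * np.asarray(spacing)
    base = np.array([0.5, 0.5, 0.12]) * extent
    seg = Segment(0, None, np.array([base, base + [0, 0, 0.7 * extent[2]]]), 0.8, 0)
    _, truth = render_angiogram(
        [seg], shape, spacing, vessel_intensity=100.0, background_intensity=0.0
    )
    parent = np.zeros(shape, dtype=bool)
    c = np.round(base / np.asarray(spacing)).astype(int)
    parent[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = True
    skel = skeletonize_to_graph(truth.vessel_mask, spacing, parent_mask=parent)
    trunk_counts = count_stems_branches(skel)

    return {
        "match_rate_pct": 100.0 * matches / n_trees,
        "n_trees": n_trees,
        "mismatches": mismatches,
        "trunk_only_counts": trunk_counts,
    }


def threshold_gap_audit(seed: int = 0, n_cases: int = 20, shape=(32, 32, 32)) -> Dict:
    """Bimodal phantoms: the selected threshold must fall inside the
    intensity gap (checked against the empirical mode edges, and by
    exhaustive enumeration of candidate thresholds inside the gap yielding
    one identical vessel set), and the suprathreshold volume curve must be
    monotone on every run."""
    in_gap = 0
    monotone = 0
    for k in range(n_cases):
        rng = np.random.default_rng(seed + k)
        data = rng.uniform(0.0, 0.2, size=shape)
        truth = np.zeros(shape, dtype=bool)
        c = np.asarray(shape) // 2
        half = 3 + k % 3
        truth[c[0] - half:c[0] + half, c[1] - half:c[1] + half, c[2] - half:c[2] + half] = True
        data[truth] = rng.uniform(0.8, 1.0, size=int(truth.sum()))
        vol = ScalarVolume(data, spacing=(0.4, 0.4, 0.4))
        roi = RegionLabelMask(np.ones(shape, dtype=np.int16), {"r": 1}, spacing=(0.4, 0.4, 0.4))
        sel = select_threshold(vol, roi)
        gap_lo = data[~truth].max()
        gap_hi = data[truth].min()
        t = sel.selected_threshold
        if gap_lo < t < gap_hi:
            # every candidate inside the gap yields the identical vessel set
            cands = [
                c_
                for c_ in sel.candidate_thresholds
                if gap_lo < c_ < gap_hi
            ]
            sets_equal = all(
                np.array_equal(data >= c_, data >= t) for c_ in cands
            )
            in_gap += bool(sets_equal)
        if np.all(np.diff(sel.volume_curve) >= 0):
            monotone += 1
    return {
        "gap_hit_rate_pct": 100.0 * in_gap / n_cases,
        "monotone_rate_pct": 100.0 * monotone / n_cases,
        "n_cases": n_cases,
    }


def icc_validation(seed: int = 0, n_tables: int = 100, n_subjects_sim: int = 200) -> Dict:
    """ICC(A,1) vs a brute-force two-way ANOVA computation on random small
    tables; exact 1 for identical scan pairs; recovery of the true
    between/total variance ratio on simulated scan-rescan data."""
    rng = np.random.default_rng(seed)

    def oracle(x):
        n, k = x.shape
        grand = x.mean()
        ssr = k * ((x.mean(axis=1) - grand) ** 2).sum()
        ssc = n * ((x.mean(axis=0) - grand) ** 2).sum()
        sse = ((x - grand) ** 2).sum() - ssr - ssc
        msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(3, 12))
        k = int(rng.integers(2, 5))
        x = rng.normal(size=(n, k)) + 1.5 * rng.normal(size=(n, 1))
        worst = max(worst, abs(icc_agreement(x).icc - oracle(x)))

    ident = rng.normal(size=(10, 1)) @ np.ones((1, 2))
    icc_ident = icc_agreement(ident).icc

    sb, sw = 2.0, 1.0
    b = rng.normal(0, sb, size=(n_subjects_sim, 1))
    x = 10.0 + b + rng.normal(0, sw, size=(n_subjects_sim, 2))
    target = sb**2 / (sb**2 + sw**2)
    sim_err = abs(icc_agreement(x).icc - target)

    return {
        "max_abs_diff_vs_anova": worst,
        "identical_pair_icc": icc_ident,
        "variance_ratio_abs_error": sim_err,
        "n_tables": n_tables,
        "n_subjects_sim": n_subjects_sim,
    }


def determinism_check(seed: int = 0, shape=(48, 48, 48)) -> Dict:
    """Run the same case config twice; the report bundles must be
    bit-identical (hashes of every artifact file)."""
    vol, truth = make_phantom_case(seed=seed, shape=shape)
    with tempfile.TemporaryDirectory() as td:
        case_dir = Path(td) / "case"
        write_phantom_case(vol, truth, case_dir)
        cfg = CaseConfig(
            volume_path=str(case_dir / "angiogram.nii.gz"),
            roi_path=str(case_dir / "regions.nii.gz"),
            legend_path=str(case_dir / "legend.yaml"),
            out_dir=str(Path(td) / "out"),
            case_id="determinism",
        )
        digests = []
        for _ in range(2):
            run_case(cfg)
            out = Path(cfg.out_dir)
            digests.append(
                {
                    p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.iterdir())
                }
            )
    return {"bit_identical": digests[0] == digests[1], "n_files": len(digests[0])}
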