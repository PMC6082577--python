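"""End-to-end parameter recovery on synthetic scenes.

These routines close the loop between the generator and the analysis: they
run the full pipeline (z-selection, ROI thresholding, size filtering,
annulus-corrected quantification, registration, tracking) on synthetic
stacks and compare what was measured against what was planted. They are the
basis of the validation command and of the acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dynamics import RigidTransform, register_rigid, track_foci, dynamics_summary
from .io import ROI, ROISet, ImageStack, select_best_z
from .quantification import quantify_foci
from .segmentation import FocusObject, SegmentationParams, segment_foci
from .synthetic import GroundTruth, SceneSpec, generate_microcolony, generate_timelapse, spot_contrast_image

__all__ = [
    "match_detections",
    "scene_roi",
    "analyze_scene",
    "frequency_recovery",
    "intensity_recovery",
    "registration_recovery",
    "dynamics_discrimination",
]


def match_detections(
    true_positions: np.ndarray,
    detected_positions: np.ndarray,
    radius_px: float = 3.0,
) -> dict:
    """Greedy closest-first one-to-one matching of detections to truth.

    Returns matched index pairs plus precision and recall. A detection
    within ``radius_px`` of an unmatched true focus is a true positive;
    leftover detections are false positives, leftover planted foci are
    misses.
    """
    true_positions = np.atleast_2d(np.asarray(true_positions, dtype=float))
    detected_positions = np.atleast_2d(np.asarray(detected_positions, dtype=float))
    nt = 0 if true_positions.size == 0 else len(true_positions)
    nd = 0 if detected_positions.size == 0 else len(detected_positions)
    pairs: list[tuple[float, int, int]] = []
    for i in range(nt):
        for j in range(nd):
            d = math.hypot(
                true_positions[i, 0] - detected_positions[j, 0],
                true_positions[i, 1] - detected_positions[j, 1],
            )
            if d <= radius_px:
                pairs.append((d, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matches: list[tuple[int, int]] = []
    for d, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        matches.append((i, j))
        used_t.add(i)
        used_d.add(j)
    tp = len(matches)
    return {
        "matches": matches,
        "n_true": nt,
        "n_detected": nd,
        "true_positives": tp,
        "precision": tp / nd if nd else 1.0,
        "recall": tp / nt if nt else 1.0,
    }


def scene_roi(truth: GroundTruth, pad_px: float = 10.0, label: str = "colony") -> ROI:
    """Rectangle ROI around all cells, the synthetic stand-in for the ROI a
    microscopist would draw around the cell group."""
    h, w = truth.spec.image_shape
    ys, xs = [], []
    for c in truth.cells:
        a, b = c.endpoints
        ys += [a[0], b[0]]
        xs += [a[1], b[1]]
    half = truth.spec.cell_width_px / 2
    y0 = max(min(ys) - half - pad_px, 0)
    y1 = min(max(ys) + half + pad_px, h - 1)
    x0 = max(min(xs) - half - pad_px, 0)
    x1 = min(max(xs) + half + pad_px, w - 1)
    return ROI.from_rect(label, (y0, x0), (y1, x1), z_range=(0, truth.spec.n_z - 1))


@dataclass
class SceneAnalysis:
    foci: list[FocusObject]
    measurements: list
    z_selected: int
    roi: ROI


def analyze_scene(
    stack: ImageStack,
    truth: GroundTruth,
    params: SegmentationParams | None = None,
    t: int = 0,
    channel: int = 0,
) -> SceneAnalysis:
    """Run the static pipeline on one frame of a synthetic scene."""
    params = params or SegmentationParams()
    roi = scene_roi(truth)
    z = select_best_z(stack, channel, t)
    foci = segment_foci(stack, ROISet([roi]), channel=channel, t=t, params=params, z=z)
    plane = stack.plane(t, z, channel)
    measurements = quantify_foci(plane, foci)
    return SceneAnalysis(foci=foci, measurements=measurements, z_selected=z, roi=roi)


def frequency_recovery(
    base_spec: SceneSpec,
    n_scenes: int,
    seed: int,
    match_radius_px: float = 3.0,
) -> dict:
    """Detected foci-per-cell over several scenes versus the planted rate.

    Aggregates detections and cell counts across ``n_scenes`` independent
    seeded scenes drawn from ``base_spec`` and matches detections to the
    planted focus positions.
    """
    total_cells = 0
    total_detected = 0
    total_true = 0
    tp = 0
    for i in range(n_scenes):
        spec = replace(base_spec, seed=int(seed + i))
        stack, truth = generate_microcolony(spec)
        analysis = analyze_scene(stack, truth)
        det = np.array([f.centroid[-2:] for f in analysis.foci], dtype=float)
        true = np.array(
            [(f.states[0].rendered_y, f.states[0].rendered_x) for f in truth.foci],
            dtype=float,
        )
        m = match_detections(true, det, radius_px=match_radius_px)
        total_cells += truth.n_cells
        total_detected += m["n_detected"]
        total_true += m["n_true"]
        tp += m["true_positives"]
    return {
        "n_cells": total_cells,
        "n_detected": total_detected,
        "n_true": total_true,
        "detected_foci_per_cell": total_detected / total_cells,
        "planted_foci_per_cell": base_spec.focus_prob_per_cell,
        "true_foci_per_cell": total_true / total_cells,
        "precision": tp / total_detected if total_detected else 1.0,
        "recall": tp / total_true if total_true else 1.0,
    }


def intensity_recovery(
    base_spec: SceneSpec,
    n_scenes: int,
    seed: int,
    background_offset: float = 0.0,
    match_radius_px: float = 3.0,
) -> dict:
    """Mean annulus-corrected intensity versus planted spot contrast.

    The planted contrast of a focus is the mean of the noiseless spot-only
    image over the same detected pixel set, minus its mean over the same
    annulus — i.e. exactly what the measurement would return on noise-free
    data. ``background_offset`` adds a constant to the whole stack before
    measuring, to probe offset invariance of the corrected intensities.
    """
    from .quantification import annulus_background, measure_focus

    measured: list[float] = []
    planted: list[float] = []
    for i in range(n_scenes):
        spec = replace(base_spec, seed=int(seed + 7919 * (i + 1)) % (2**31))
        stack, truth = generate_microcolony(spec)
        if background_offset:
            pixels = np.clip(
                stack.pixels.astype(np.float64) + background_offset, 0, 65535
            ).astype(np.uint16)
            stack = ImageStack(
                pixels=pixels, pixel_size_um=stack.pixel_size_um,
                z_step_um=stack.z_step_um, frame_interval_s=stack.frame_interval_s,
                channel_names=stack.channel_names,
            )
        analysis = analyze_scene(stack, truth)
        det = np.array([f.centroid[-2:] for f in analysis.foci], dtype=float)
        true = np.array(
            [(f.states[0].rendered_y, f.states[0].rendered_x) for f in truth.foci],
            dtype=float,
        )
        m = match_detections(true, det, radius_px=match_radius_px)
        spot_img = spot_contrast_image(spec, truth)
        all_mask = np.zeros(spec.image_shape, dtype=bool)
        for f in analysis.foci:
            all_mask[tuple(f.pixel_set.T)] = True
        by_id = {f.id: f for f in analysis.foci}
        meas_by_id = {mm.focus_id: mm for mm in analysis.measurements}
        for ti, dj in m["matches"]:
            focus = by_id[analysis.foci[dj].id]
            mm = meas_by_id[focus.id]
            true_mean = measure_focus(spot_img, focus)
            true_bg = annulus_background(spot_img, focus, all_mask)
            planted.append(true_mean - true_bg)
            measured.append(mm.corrected_intensity)
    measured_arr = np.asarray(measured)
    planted_arr = np.asarray(planted)
    rel_err = float(
        abs(measured_arr.mean() - planted_arr.mean()) / planted_arr.mean()
    )
    return {
        "n_foci": len(measured),
        "mean_measured": float(measured_arr.mean()),
        "mean_planted": float(planted_arr.mean()),
        "relative_error": rel_err,
    }


def registration_recovery(base_spec: SceneSpec, seed: int) -> dict:
    """Recover planted rigid drift from a synthetic time lapse.

    Registers the highest-contrast fluorescence planes and composes each
    recovered correction with the planted cumulative drift; a perfect
    recovery leaves the identity. Reports the worst residual translation
    and rotation across frames.
    """
    spec = replace(base_spec, seed=int(seed))
    stack, truth = generate_timelapse(spec)
    frames = []
    for t in range(stack.n_frames):
        z = select_best_z(stack, 0, t)
        frames.append(stack.plane(t, z, 0).astype(np.float64))
    transforms, _ = register_rigid(frames)
    resid_t = []
    resid_r = []
    for rec, planted in zip(transforms, truth.drift):
        residual = rec.compose(planted)  # correction after planted drift
        dt, dr = residual.magnitude()
        resid_t.append(dt)
        resid_r.append(dr)
    return {
        "max_translation_error_px": float(max(resid_t)),
        "max_rotation_error_deg": float(max(resid_r)),
        "n_frames": stack.n_frames,
        "transforms": transforms,
    }


def _timelapse_static_fraction(
    spec: SceneSpec,
    link_radius_px: float = 15.0,
    site_radius_px: float = 3.0,
    static_threshold: float = 0.7,
    max_gap: int = 1,
) -> float:
    stack, truth = generate_timelapse(spec)
    roi = scene_roi(truth)
    per_frame: list[list[FocusObject]] = []
    for t in range(stack.n_frames):
        z = select_best_z(stack, 0, t)
        foci = segment_foci(stack, ROISet([roi]), channel=0, t=t, z=z)
        per_frame.append(foci)
    tracks = track_foci(per_frame, link_radius_px=link_radius_px, max_gap=max_gap)
    if not tracks:
        return float("nan")
    summary = dynamics_summary(
        tracks, site_radius_px=site_radius_px, static_threshold=static_threshold
    )
    return summary["static_fraction"]


def dynamics_discrimination(
    static_spec: SceneSpec,
    relocating_spec: SceneSpec,
    n_replicates: int,
    seed: int,
    **tracking_kwargs,
) -> dict:
    """Does the static-track fraction separate the two planted regimes?

    Runs ``n_replicates`` seeded replicates per regime and reports the
    per-regime static fractions plus the AUC of the statistic for telling
    the regimes apart (probability, over all replicate pairs, that the
    same-site regime scores higher; ties count half).
    """
    static_fracs = []
    reloc_fracs = []
    for i in range(n_replicates):
        s_spec = replace(static_spec, seed=int(seed + 2 * i))
        r_spec = replace(relocating_spec, seed=int(seed + 2 * i + 1))
        static_fracs.append(_timelapse_static_fraction(s_spec, **tracking_kwargs))
        reloc_fracs.append(_timelapse_static_fraction(r_spec, **tracking_kwargs))
    static_arr = np.asarray(static_fracs)
    reloc_arr = np.asarray(reloc_fracs)
    wins = (static_arr[:, None] > reloc_arr[None, :]).sum()
    ties = (static_arr[:, None] == reloc_arr[None, :]).sum()
    auc = (wins + 0.5 * ties) / (len(static_arr) * len(reloc_arr))
    return {
        "static_regime_fractions": static_fracs,
        "relocating_regime_fractions": reloc_fracs,
        "mean_static_fraction_same_site": float(np.nanmean(static_arr)),
        "mean_static_fraction_relocating": float(np.nanmean(reloc_arr)),
        "auc": float(auc),
        "n_replicates": n_replicates,
    }
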