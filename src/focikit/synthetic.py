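"""Synthetic fluorescence microcolonies with ground truth.

Generates seeded, fully reproducible image stacks that emulate widefield
acquisition of rod-shaped bacteria carrying diffraction-limited fluorescent
foci: 512x512 fields, a z-stack whose off-focus sections are progressively
defocused, a fluorescence channel plus a flat DIC placeholder, Poisson shot
noise and Gaussian read noise quantised to 16-bit camera counts.

Cells are non-overlapping spherocylinders placed in a central colony (or
uniformly); each cell carries at most one focus with a configurable
probability. In time-lapse mode foci alternate between assembled periods
(geometric lifetimes) and dark periods, and on each re-assembly relocate to
a new site within the cell with probability ``relocation_prob`` — the
behavioural axis that distinguishes rapid-turnover from same-site-reassembly
regimes. Rigid stage drift is applied cumulatively per frame. Every planted
quantity is recorded in a :class:`GroundTruth` object, the reference for
parameter-recovery validation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .dynamics import RigidTransform
from .io import ImageStack

__all__ = [
    "SceneSpec",
    "CellRecord",
    "FocusFrameState",
    "FocusRecord",
    "GroundTruth",
    "generate_microcolony",
    "generate_timelapse",
    "export_ground_truth",
    "load_ground_truth",
    "spot_contrast_image",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping cells."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene; every field has a stated default.

    Photometry defaults are chosen so the in-cell level (background +
    cytoplasm = 400 counts) and typical spot peaks (~2900-5500 counts) span
    the rendering window used for the real data. ``focus_prob_per_cell``
    takes the observed per-cell focus frequencies (0.55 wild-type-like,
    0.76 phosphatase-mutant-like) as its regimes.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_z: int = 11
    n_cells: int = 150
    cell_length_um: float = 2.5
    cell_width_um: float = 0.8
    pixel_size_um: float = 0.065
    z_step_um: float = 0.25
    focus_prob_per_cell: float = 0.55
    focus_amplitude_median: float = 2500.0
    focus_amplitude_sigma: float = 0.3  # lognormal sigma, log scale
    psf_sigma_px: float = 1.3
    cytoplasm_level: float = 280.0
    background_level: float = 120.0
    poisson_gain: float = 1.0
    read_noise_sd: float = 5.0
    enable_noise: bool = True
    layout: str = "colony"  # or "uniform"
    include_dic: bool = True
    defocus_sigma_per_um: float = 2.0  # extra PSF sigma per um defocus
    # time-lapse parameters
    n_frames: int = 21
    frame_interval_s: float = 90.0
    focus_lifetime_frames: float = 5.0  # geometric mean assembled period
    dark_frames_mean: float = 1.3  # geometric mean dark period
    relocation_prob: float = 0.5
    min_relocation_px: float = 6.0
    dropout_prob: float = 0.03  # transient one-frame disappearance
    focus_jitter_px: float = 0.2
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)  # dy, dx, deg
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.focus_prob_per_cell <= 1.0:
            raise ValueError("focus_prob_per_cell must be in [0, 1]")
        if not 0.0 <= self.relocation_prob <= 1.0:
            raise ValueError("relocation_prob must be in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        for name in ("cytoplasm_level", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.layout not in ("colony", "uniform"):
            raise ValueError("layout must be 'colony' or 'uniform'")

    @property
    def cell_length_px(self) -> float:
        return self.cell_length_um / self.pixel_size_um

    @property
    def cell_width_px(self) -> float:
        return self.cell_width_um / self.pixel_size_um


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple[float, float]  # (y, x), undrifted scene coordinates
    orientation_deg: float
    length_px: float
    width_px: float

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """End points of the cell's axis segment (cylinder part)."""
        half = (self.length_px - self.width_px) / 2
        d = np.array(
            [math.sin(math.radians(self.orientation_deg)),
             math.cos(math.radians(self.orientation_deg))]
        )
        c = np.array(self.centroid)
        return c - half * d, c + half * d


@dataclass
class FocusFrameState:
    frame: int
    y: float  # undrifted scene coordinates
    x: float
    visible: bool
    rendered_y: float  # after drift, i.e. where the spot appears on camera
    rendered_x: float


@dataclass
class FocusRecord:
    focus_id: int
    cell_id: int
    amplitude: float
    states: list[FocusFrameState] = field(default_factory=list)
    relocation_frames: list[int] = field(default_factory=list)
    sites: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    cells: list[CellRecord]
    foci: list[FocusRecord]
    drift: list[RigidTransform]  # cumulative transform per frame
    per_frame_focus_count: list[int]  # visible foci per frame
    n_cells: int
    spec: SceneSpec


# ---------------------------------------------------------------------------
# geometry helpers


def _segment_points(cell: CellRecord, k: int = 9) -> np.ndarray:
    a, b = cell.endpoints
    ts = np.linspace(0.0, 1.0, k)[:, None]
    return a[None, :] * (1 - ts) + b[None, :] * ts


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> list[CellRecord]:
    h, w = spec.image_shape
    length, width = spec.cell_length_px, spec.cell_width_px
    margin = length / 2 + 2
    if spec.layout == "colony":
        # colony radius sized for ~2.5x the summed cell footprint
        area = spec.n_cells * length * width
        radius = math.sqrt(2.5 * area / math.pi)
        centre = np.array([h / 2, w / 2])
    cells: list[CellRecord] = []
    existing_pts: list[np.ndarray] = []
    budget = 300 * max(spec.n_cells, 1)
    attempts = 0
    while len(cells) < spec.n_cells:
        attempts += 1
        if attempts > budget:
            raise PlacementError(
                f"placed {len(cells)}/{spec.n_cells} cells within the retry budget; "
                "reduce n_cells or enlarge the field"
            )
        if spec.layout == "colony":
            pos = centre + rng.normal(0.0, radius / 1.5, size=2)
        else:
            pos = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
        if not (margin <= pos[0] <= h - margin and margin <= pos[1] <= w - margin):
            continue
        theta = rng.uniform(0.0, 180.0)
        cand = CellRecord(
            cell_id=len(cells), centroid=(float(pos[0]), float(pos[1])),
            orientation_deg=float(theta), length_px=length, width_px=width,
        )
        pts = _segment_points(cand)
        ok = True
        if existing_pts:
            allpts = np.concatenate(existing_pts)  # (m, 2)
            d = np.linalg.norm(allpts[:, None, :] - pts[None, :, :], axis=2)
            if d.min() < width + 1.0:
                ok = False
        if ok:
            cells.append(cand)
            existing_pts.append(pts)
    return cells


def _sample_site(
    cell: CellRecord, rng: np.random.Generator,
    avoid: tuple[float, float] | None = None, min_dist: float = 0.0,
) -> tuple[float, float]:
    """Random focus site inside a cell, optionally away from a previous site."""
    a, b = cell.endpoints
    d = b - a
    n = np.array([-d[1], d[0]])
    n = n / (np.linalg.norm(n) + 1e-12)
    best = None
    best_dist = -1.0
    for _ in range(100):
        t = rng.uniform(0.0, 1.0)
        lateral = rng.uniform(-cell.width_px / 4, cell.width_px / 4)
        p = a + t * d + lateral * n
        if avoid is None:
            return float(p[0]), float(p[1])
        dist = math.hypot(p[0] - avoid[0], p[1] - avoid[1])
        if dist >= min_dist:
            return float(p[0]), float(p[1])
        if dist > best_dist:
            best, best_dist = p, dist
    return float(best[0]), float(best[1])  # farthest candidate found


# ---------------------------------------------------------------------------
# rendering


def _render_cytoplasm(
    spec: SceneSpec, cells: list[CellRecord], drift: RigidTransform
) -> np.ndarray:
    """Binary-ish cytoplasm image (cell interior = cytoplasm_level), pre-PSF."""
    h, w = spec.image_shape
    img = np.zeros((h, w), dtype=np.float64)
    half_w = spec.cell_width_px / 2
    for cell in cells:
        a, b = cell.endpoints
        pts = np.stack([a, b])
        pts = drift.apply_to_points(pts, spec.image_shape)
        a, b = pts[0], pts[1]
        y0 = max(int(np.floor(min(a[0], b[0]) - half_w - 1)), 0)
        y1 = min(int(np.ceil(max(a[0], b[0]) + half_w + 1)), h - 1)
        x0 = max(int(np.floor(min(a[1], b[1]) - half_w - 1)), 0)
        x1 = min(int(np.ceil(max(a[1], b[1]) + half_w + 1)), w - 1)
        if y1 < y0 or x1 < x0:
            continue
        yy, xx = np.meshgrid(
            np.arange(y0, y1 + 1, dtype=float),
            np.arange(x0, x1 + 1, dtype=float),
            indexing="ij",
        )
        d = b - a
        seg2 = d @ d
        py = yy - a[0]
        px = xx - a[1]
        t = np.clip((py * d[0] + px * d[1]) / (seg2 + 1e-12), 0.0, 1.0)
        dist = np.hypot(py - t * d[0], px - t * d[1])
        inside = dist <= half_w
        img[y0 : y1 + 1, x0 : x1 + 1][inside] = spec.cytoplasm_level
    return img


def _add_spots(
    img: np.ndarray,
    positions: list[tuple[float, float]],
    amplitudes: list[float],
    sigma: float,
    peak_scale: float = 1.0,
) -> None:
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    for (y, x), amp in zip(positions, amplitudes):
        y0, y1 = max(int(y) - r, 0), min(int(y) + r, h - 1)
        x0, x1 = max(int(x) - r, 0), min(int(x) + r, w - 1)
        if y1 < y0 or x1 < x0:
            continue
        yy, xx = np.meshgrid(
            np.arange(y0, y1 + 1, dtype=float),
            np.arange(x0, x1 + 1, dtype=float),
            indexing="ij",
        )
        img[y0 : y1 + 1, x0 : x1 + 1] += (
            amp * peak_scale
            * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
        )


def _render_fluor_plane(
    spec: SceneSpec,
    cells: list[CellRecord],
    positions: list[tuple[float, float]],
    amplitudes: list[float],
    z: int,
    drift: RigidTransform,
) -> np.ndarray:
    """Noiseless fluorescence plane at z-section ``z`` (defocus applied)."""
    z_mid = (spec.n_z - 1) / 2
    defocus_um = abs(z - z_mid) * spec.z_step_um
    # defocus grows the PSF sigma; flux is conserved so peaks attenuate
    extra_sigma = spec.defocus_sigma_per_um * defocus_um
    sigma_z = math.hypot(spec.psf_sigma_px, extra_sigma)
    cyto = _render_cytoplasm(spec, cells, drift)
    cyto = ndi.gaussian_filter(cyto, sigma=sigma_z)
    img = np.full(spec.image_shape, spec.background_level, dtype=np.float64) + cyto
    peak_scale = (spec.psf_sigma_px / sigma_z) ** 2
    _add_spots(img, positions, amplitudes, sigma_z, peak_scale)
    return img


def _apply_noise(
    plane: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.enable_noise:
        gain = max(spec.poisson_gain, 1e-9)
        plane = rng.poisson(np.clip(plane, 0, None) / gain) * gain
        plane = plane + rng.normal(0.0, spec.read_noise_sd, size=plane.shape)
    return np.clip(np.round(plane), 0, 65535).astype(np.uint16)


def spot_contrast_image(
    spec: SceneSpec, truth: GroundTruth, frame: int = 0
) -> np.ndarray:
    """Noiseless spot-only contribution at the in-focus plane of one frame.

    This is the planted contrast field against which measured
    background-corrected intensities are validated.
    """
    img = np.zeros(spec.image_shape, dtype=np.float64)
    positions, amps = [], []
    for f in truth.foci:
        for s in f.states:
            if s.frame == frame and s.visible:
                positions.append((s.rendered_y, s.rendered_x))
                amps.append(f.amplitude)
    _add_spots(img, positions, amps, spec.psf_sigma_px)
    return img


# ---------------------------------------------------------------------------
# generators


def _assemble_stack(
    spec: SceneSpec,
    cells: list[CellRecord],
    frames_foci: list[tuple[list[tuple[float, float]], list[float]]],
    drift: list[RigidTransform],
    rng: np.random.Generator,
) -> ImageStack:
    n_t = len(frames_foci)
    n_c = 2 if spec.include_dic else 1
    h, w = spec.image_shape
    pixels = np.zeros((n_t, spec.n_z, n_c, h, w), dtype=np.uint16)
    for t in range(n_t):
        positions, amps = frames_foci[t]
        for z in range(spec.n_z):
            plane = _render_fluor_plane(spec, cells, positions, amps, z, drift[t])
            pixels[t, z, 0] = _apply_noise(plane, spec, rng)
        if spec.include_dic:
            pixels[t, :, 1] = 1000
    names = ["GFP", "DIC"] if spec.include_dic else ["GFP"]
    return ImageStack(
        pixels=pixels,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
        frame_interval_s=spec.frame_interval_s if n_t > 1 else 1.0,
        channel_names=names,
    )


def generate_microcolony(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """One static scene: placed cells, planted foci, rendered z-stack.

    Deterministic for a fixed spec (including its seed): the same spec
    yields bit-identical pixels and ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    foci: list[FocusRecord] = []
    positions: list[tuple[float, float]] = []
    amps: list[float] = []
    identity = RigidTransform()
    for cell in cells:
        if rng.random() < spec.focus_prob_per_cell:
            site = _sample_site(cell, rng)
            amp = float(
                spec.focus_amplitude_median
                * math.exp(rng.normal(0.0, spec.focus_amplitude_sigma))
            )
            rec = FocusRecord(
                focus_id=len(foci), cell_id=cell.cell_id, amplitude=amp,
                sites=[site],
            )
            rec.states.append(
                FocusFrameState(
                    frame=0, y=site[0], x=site[1], visible=True,
                    rendered_y=site[0], rendered_x=site[1],
                )
            )
            foci.append(rec)
            positions.append(site)
            amps.append(amp)
    stack = _assemble_stack(spec, cells, [(positions, amps)], [identity], rng)
    truth = GroundTruth(
        cells=cells, foci=foci, drift=[identity],
        per_frame_focus_count=[len(foci)], n_cells=len(cells), spec=spec,
    )
    return stack, truth


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric draw on {1, 2, ...} with the given mean (>= 1)."""
    p = 1.0 / max(mean, 1.0)
    return int(rng.geometric(p))


def generate_timelapse(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse scene with focus assembly/disassembly and drift.

    Each focus-bearing cell alternates assembled periods (geometric, mean
    ``focus_lifetime_frames``) with dark periods (geometric, mean
    ``dark_frames_mean``); each re-assembly relocates with probability
    ``relocation_prob`` to a site at least ``min_relocation_px`` away,
    otherwise reuses the same site. Independent one-frame dropouts model
    transient disappearance of a still-assembled sheath. Cumulative rigid
    drift moves the whole scene; ground truth records both the undrifted and
    the rendered (camera-frame) position of every focus at every frame.
    """
    if spec.n_frames < 2:
        raise ValueError("a time lapse needs n_frames >= 2")
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    step = RigidTransform(
        dy=spec.drift_per_frame[0], dx=spec.drift_per_frame[1],
        theta=spec.drift_per_frame[2],
    )
    drift = [RigidTransform(frame_index=0)]
    for t in range(1, spec.n_frames):
        d = step.compose(drift[-1])
        drift.append(RigidTransform(dy=d.dy, dx=d.dx, theta=d.theta, frame_index=t))
    foci: list[FocusRecord] = []
    for cell in cells:
        if rng.random() >= spec.focus_prob_per_cell:
            continue
        rec = FocusRecord(focus_id=len(foci), cell_id=cell.cell_id,
                          amplitude=float(
                              spec.focus_amplitude_median
                              * math.exp(rng.normal(0.0, spec.focus_amplitude_sigma))
                          ))
        site = _sample_site(cell, rng)
        rec.sites.append(site)
        t = 0
        # random initial phase: start mid-lifetime or mid-dark
        assembled = rng.random() < (
            spec.focus_lifetime_frames
            / (spec.focus_lifetime_frames + spec.dark_frames_mean)
        )
        remaining = _geometric(
            rng, spec.focus_lifetime_frames if assembled else spec.dark_frames_mean
        )
        while t < spec.n_frames:
            if assembled:
                jitter = rng.normal(0.0, spec.focus_jitter_px, size=2)
                y, x = site[0] + jitter[0], site[1] + jitter[1]
                visible = rng.random() >= spec.dropout_prob
                ry, rx = drift[t].apply_to_points(
                    np.array([[y, x]]), spec.image_shape
                )[0]
                rec.states.append(
                    FocusFrameState(frame=t, y=float(y), x=float(x),
                                    visible=bool(visible),
                                    rendered_y=float(ry), rendered_x=float(rx))
                )
            remaining -= 1
            t += 1
            if remaining == 0:
                if assembled:
                    assembled = False
                    remaining = _geometric(rng, spec.dark_frames_mean)
                else:
                    assembled = True
                    remaining = _geometric(rng, spec.focus_lifetime_frames)
                    if rng.random() < spec.relocation_prob:
                        site = _sample_site(
                            cell, rng, avoid=site, min_dist=spec.min_relocation_px
                        )
                        if t < spec.n_frames:
                            rec.relocation_frames.append(t)
                            rec.sites.append(site)
        if rec.states:
            foci.append(rec)
    frames_foci = []
    per_frame_count = []
    for t in range(spec.n_frames):
        positions, amps = [], []
        for rec in foci:
            for s in rec.states:
                if s.frame == t and s.visible:
                    positions.append((s.rendered_y, s.rendered_x))
                    amps.append(rec.amplitude)
        frames_foci.append((positions, amps))
        per_frame_count.append(len(positions))
    stack = _assemble_stack(spec, cells, frames_foci, drift, rng)
    truth = GroundTruth(
        cells=cells, foci=foci, drift=drift,
        per_frame_focus_count=per_frame_count, n_cells=len(cells), spec=spec,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# ground-truth export


def export_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Write ground truth as CSV tables plus a JSON summary.

    Files: ``cells.csv``, ``foci.csv`` (one row per focus per frame),
    ``drift.csv``, ``truth.json`` (scene spec, counts, relocation events).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "centroid_y": c.centroid[0],
                "centroid_x": c.centroid[1],
                "orientation_deg": c.orientation_deg,
                "length_px": c.length_px,
                "width_px": c.width_px,
            }
            for c in truth.cells
        ],
        columns=["cell_id", "centroid_y", "centroid_x", "orientation_deg",
                 "length_px", "width_px"],
    )
    cells.to_csv(outdir / "cells.csv", index=False)
    foci_rows = []
    for f in truth.foci:
        for s in f.states:
            foci_rows.append(
                {
                    "focus_id": f.focus_id,
                    "cell_id": f.cell_id,
                    "frame": s.frame,
                    "y": s.y,
                    "x": s.x,
                    "visible": int(s.visible),
                    "rendered_y": s.rendered_y,
                    "rendered_x": s.rendered_x,
                    "amplitude": f.amplitude,
                }
            )
    pd.DataFrame(
        foci_rows,
        columns=["focus_id", "cell_id", "frame", "y", "x", "visible",
                 "rendered_y", "rendered_x", "amplitude"],
    ).to_csv(outdir / "foci.csv", index=False)
    pd.DataFrame(
        [
            {"frame": d.frame_index, "dy": d.dy, "dx": d.dx, "theta_deg": d.theta}
            for d in truth.drift
        ],
        columns=["frame", "dy", "dx", "theta_deg"],
    ).to_csv(outdir / "drift.csv", index=False)
    payload = {
        "spec": dataclasses.asdict(truth.spec),
        "n_cells": truth.n_cells,
        "n_foci": len(truth.foci),
        "per_frame_focus_count": truth.per_frame_focus_count,
        "relocations": {
            str(f.focus_id): f.relocation_frames for f in truth.foci
        },
        "sites": {
            str(f.focus_id): [[y, x] for y, x in f.sites] for f in truth.foci
        },
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=1) + "\n")


def load_ground_truth(outdir: str | Path) -> GroundTruth:
    """Read back what :func:`export_ground_truth` wrote."""
    outdir = Path(outdir)
    payload = json.loads((outdir / "truth.json").read_text())
    spec_dict = payload["spec"]
    for key in ("image_shape", "drift_per_frame"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = SceneSpec(**spec_dict)
    cells_df = pd.read_csv(outdir / "cells.csv")
    cells = [
        CellRecord(
            cell_id=int(r.cell_id), centroid=(float(r.centroid_y), float(r.centroid_x)),
            orientation_deg=float(r.orientation_deg),
            length_px=float(r.length_px), width_px=float(r.width_px),
        )
        for r in cells_df.itertuples()
    ]
    foci_df = pd.read_csv(outdir / "foci.csv")
    foci: dict[int, FocusRecord] = {}
    for r in foci_df.itertuples():
        fid = int(r.focus_id)
        if fid not in foci:
            foci[fid] = FocusRecord(
                focus_id=fid, cell_id=int(r.cell_id), amplitude=float(r.amplitude),
                relocation_frames=[int(v) for v in payload["relocations"][str(fid)]],
                sites=[(float(y), float(x)) for y, x in payload["sites"][str(fid)]],
            )
        foci[fid].states.append(
            FocusFrameState(
                frame=int(r.frame), y=float(r.y), x=float(r.x),
                visible=bool(r.visible),
                rendered_y=float(r.rendered_y), rendered_x=float(r.rendered_x),
            )
        )
    drift_df = pd.read_csv(outdir / "drift.csv")
    drift = [
        RigidTransform(dy=float(r.dy), dx=float(r.dx), theta=float(r.theta_deg),
                       frame_index=int(r.frame))
        for r in drift_df.itertuples()
    ]
    return GroundTruth(
        cells=cells,
        foci=[foci[k] for k in sorted(foci)],
        drift=drift,
        per_frame_focus_count=[int(v) for v in payload["per_frame_focus_count"]],
        n_cells=int(payload["n_cells"]),
        spec=spec,
    )
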