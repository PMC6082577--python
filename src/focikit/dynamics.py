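"""Time-lapse analysis: drift correction, temporal projection, tracking.

Drift is modelled as a rigid-body motion (translation + rotation about the
image centre). Each frame is registered to the previous one by phase
correlation, the per-step corrections are composed to frame 0, and each
composed transform is then refined by direct least-squares on intensities.

The temporal colour-coded projection tints each rendered frame with a
time-indexed colour from a red-to-blue hue sweep and superimposes frames by
per-channel maximum, so a pixel fluorescent at many time points blends
toward white while a transient focus keeps the colour of its frame.

Focus tracking links detections frame-to-frame by greedy nearest-neighbour
assignment with a bounded gap, then scores each track's tendency to stay at
one site (site persistence) versus relocating across the cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize
from skimage.registration import phase_cross_correlation

from .segmentation import FocusObject

__all__ = [
    "RigidTransform",
    "RenderWindow",
    "TemporalProjection",
    "FocusTrack",
    "register_rigid",
    "clamp_render",
    "default_lut",
    "temporal_projection",
    "track_foci",
    "annotate_track_sites",
    "dynamics_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion ``p -> R(theta) (p - c) + c + (dy, dx)`` about the
    image centre ``c``; ``theta`` in degrees, positive = y-towards-x."""

    dy: float = 0.0
    dx: float = 0.0
    theta: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.dy, self.dx, self.theta))):
            raise ValueError("transform parameters must be finite")
        if abs(self.theta) >= 90:
            raise ValueError("|theta| must be < 90 degrees")

    def _rot(self) -> np.ndarray:
        r = math.radians(self.theta)
        return np.array(
            [[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]]
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        ra = self._rot()
        t = ra @ np.array([other.dy, other.dx]) + np.array([self.dy, self.dx])
        return RigidTransform(
            dy=float(t[0]), dx=float(t[1]),
            theta=self.theta + other.theta, frame_index=self.frame_index,
        )

    def inverse(self) -> "RigidTransform":
        r = self._rot()
        t = -r.T @ np.array([self.dy, self.dx])
        return RigidTransform(
            dy=float(t[0]), dx=float(t[1]), theta=-self.theta,
            frame_index=self.frame_index,
        )

    def apply_to_points(
        self, points: np.ndarray, shape: tuple[int, int]
    ) -> np.ndarray:
        """Map ``(y, x)`` points under the forward transform."""
        c = (np.array(shape, dtype=float) - 1) / 2
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - c) @ self._rot().T + c + np.array([self.dy, self.dx])

    def apply_to_image(
        self, image: np.ndarray, fill: float | None = None, order: int = 1
    ) -> np.ndarray:
        """Resample an image so its content moves under the transform.

        ``output(p) = input(T^{-1}(p))`` with bilinear interpolation;
        out-of-frame pixels are filled with the frame's median unless
        ``fill`` is given.
        """
        image = np.asarray(image, dtype=np.float64)
        if fill is None:
            fill = float(np.median(image))
        c = (np.array(image.shape, dtype=float) - 1) / 2
        r = self._rot()
        # output[o] = input[M o + off] with M = R^T, off = c - R^T (c + t)
        offset = c - r.T @ (c + np.array([self.dy, self.dx]))
        return ndi.affine_transform(
            image, r.T, offset=offset, order=order, mode="constant", cval=fill
        )

    def magnitude(self) -> tuple[float, float]:
        """(translation length in px, |rotation| in degrees)."""
        return math.hypot(self.dy, self.dx), abs(self.theta)


@dataclass(frozen=True)
class RenderWindow:
    """Display window in camera counts; defaults render all foci visibly."""

    lo: float = 400.0
    hi: float = 5500.0

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("window hi must exceed lo")


def clamp_render(plane: np.ndarray, window: RenderWindow | None = None) -> np.ndarray:
    """Normalise intensities into [0, 1]: ``(I - lo) / (hi - lo)``, clipped."""
    window = window or RenderWindow()
    plane = np.asarray(plane, dtype=np.float64)
    return np.clip((plane - window.lo) / (window.hi - window.lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# registration


def _ssd_valid(ref: np.ndarray, moving: np.ndarray, params, margin: int = 4) -> float:
    """SSD between ref and the warped moving frame over valid interior pixels."""
    dy, dx, theta = params
    t = RigidTransform(dy=dy, dx=dx, theta=theta)
    warped = t.apply_to_image(moving)
    valid = t.apply_to_image(np.ones_like(moving), fill=0.0) > 0.999
    valid[:margin] = valid[-margin:] = False
    valid[:, :margin] = valid[:, -margin:] = False
    if not valid.any():
        return np.inf
    d = (warped - ref)[valid]
    return float(np.mean(d * d))


def register_rigid(
    frames: list[np.ndarray] | np.ndarray,
    max_rotation_deg: float = 10.0,
    refine: bool = True,
    upsample_factor: int = 20,
    clip_percentile: float | None = 95.0,
) -> tuple[list[RigidTransform], np.ndarray]:
    """Estimate and apply per-frame rigid drift corrections.

    Each frame is registered to its predecessor by phase-correlation
    translation; the per-step corrections are composed to frame 0 and then
    refined (translation + bounded rotation) by Powell minimisation of the
    masked intensity SSD against frame 0. Returns the correction transform
    per frame (identity for frame 0) and the aligned stack.

    Estimation runs on intensities clipped at the ``clip_percentile`` of
    frame 0 (pass ``None`` to disable): bright foci assemble, move and
    disappear between frames, and uncapped they dominate the least-squares
    criterion and drag the alignment; clipping lets the static cell bodies
    anchor it. The returned aligned stack keeps the original intensities.

    A single frame yields the identity; featureless frames also yield the
    identity, with a warning, since there is nothing to register against.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frames must share one shape")
    if clip_percentile is not None and frames[0].std() > 0:
        cap = np.percentile(frames[0], clip_percentile)
        est_frames = [np.minimum(f, cap) for f in frames]
    else:
        est_frames = frames
    transforms: list[RigidTransform] = [RigidTransform(frame_index=0)]
    ref = est_frames[0]
    featureless_ref = ref.std() == 0
    for t_idx in range(1, len(frames)):
        prev, cur = est_frames[t_idx - 1], est_frames[t_idx]
        if cur.std() == 0 or prev.std() == 0:
            logger.warning("frame %d featureless; assuming identity drift", t_idx)
            step = RigidTransform(frame_index=t_idx)
        else:
            shift, _, _ = phase_cross_correlation(
                prev, cur, upsample_factor=upsample_factor, normalization=None
            )
            step = RigidTransform(dy=float(shift[0]), dx=float(shift[1]),
                                  frame_index=t_idx)
        # correction for frame t = (correction for t-1) ∘ (step t -> t-1)
        composed = transforms[t_idx - 1].compose(step)
        composed = RigidTransform(
            dy=composed.dy, dx=composed.dx, theta=composed.theta, frame_index=t_idx
        )
        if refine and not featureless_ref and cur.std() > 0:
            x0 = np.array([composed.dy, composed.dx, composed.theta])
            res = optimize.minimize(
                lambda p: _ssd_valid(ref, cur, p),
                x0,
                method="Powell",
                bounds=[
                    (x0[0] - 3, x0[0] + 3),
                    (x0[1] - 3, x0[1] + 3),
                    (max(-max_rotation_deg, x0[2] - 3), min(max_rotation_deg, x0[2] + 3)),
                ],
                options={"xtol": 1e-4, "ftol": 1e-8},
            )
            composed = RigidTransform(
                dy=float(res.x[0]), dx=float(res.x[1]), theta=float(res.x[2]),
                frame_index=t_idx,
            )
        transforms.append(composed)
    aligned = np.stack(
        [t.apply_to_image(f) for t, f in zip(transforms, frames)]
    )
    return transforms, aligned


# ---------------------------------------------------------------------------
# temporal projection


def default_lut(n_frames: int) -> np.ndarray:
    """Evenly spaced hue sweep red (0 deg) to blue (240 deg), full S/V.

    The first frame is pure red and the last pure blue; a single frame is
    rendered in red.
    """
    from matplotlib.colors import hsv_to_rgb

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames == 1:
        hues = np.array([0.0])
    else:
        hues = np.linspace(0.0, 240.0 / 360.0, n_frames)
    hsv = np.stack([hues, np.ones_like(hues), np.ones_like(hues)], axis=1)
    return hsv_to_rgb(hsv)


@dataclass
class TemporalProjection:
    rgb: np.ndarray  # (h, w, 3) in [0, 1]
    lut: np.ndarray  # (n_frames, 3)
    n_frames: int

    def __post_init__(self) -> None:
        if len(self.lut) != self.n_frames:
            raise ValueError("lut length must equal n_frames")
        first, last = self.lut[0], self.lut[-1]
        if not (first[0] >= first[1] and first[0] >= first[2]):
            raise ValueError("first LUT colour must be red-dominant")
        if self.n_frames > 1 and not (last[2] >= last[0] and last[2] >= last[1]):
            raise ValueError("last LUT colour must be blue-dominant")


def temporal_projection(
    frames: list[np.ndarray] | np.ndarray,
    window: RenderWindow | None = None,
    lut: np.ndarray | None = None,
    blend: str = "max",
) -> TemporalProjection:
    """Colour-code frames by time and superimpose them.

    Each frame is rendered into [0, 1] through the window, multiplied by its
    LUT colour, and combined per colour channel by maximum (default) or by
    clipped addition. Persistent signal accumulates all hues and blends
    toward white; signal present in a single frame keeps that frame's hue.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("frames must be a (t, y, x) array or list of planes")
    n = frames.shape[0]
    lut = default_lut(n) if lut is None else np.asarray(lut, dtype=float)
    if len(lut) != n:
        raise ValueError(f"lut has {len(lut)} colours for {n} frames")
    rendered = clamp_render(frames, window)  # (t, y, x)
    tinted = rendered[..., None] * lut[:, None, None, :]  # (t, y, x, 3)
    if blend == "max":
        rgb = tinted.max(axis=0)
    elif blend == "add":
        rgb = np.clip(tinted.sum(axis=0), 0.0, 1.0)
    else:
        raise ValueError(f"unknown blend {blend!r}")
    return TemporalProjection(rgb=rgb, lut=lut, n_frames=n)


# ---------------------------------------------------------------------------
# tracking


@dataclass
class TrackEntry:
    frame: int
    centroid: tuple[float, float]
    intensity: float | None = None


@dataclass
class FocusTrack:
    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    gap_frames: list[int] = field(default_factory=list)
    # filled by annotate_track_sites:
    modal_site: tuple[float, float] | None = None
    site_persistence: float | None = None
    n_relocations: int | None = None

    @property
    def frames(self) -> list[int]:
        return [e.frame for e in self.entries]

    @property
    def span_frames(self) -> int:
        f = self.frames
        return f[-1] - f[0] + 1

    @property
    def lifetime(self) -> int:
        return len(self.entries)


def track_foci(
    per_frame_foci: list[list[FocusObject]],
    link_radius_px: float,
    max_gap: int = 1,
    intensities: list[list[float]] | None = None,
) -> list[FocusTrack]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    At each frame, candidate (track, detection) pairs within
    ``link_radius_px`` of the track's last position are linked closest pair
    first, each detection and each track used once; a track stays linkable
    across up to ``max_gap`` consecutive missing frames. Every detection
    ends up in exactly one track.
    """
    if link_radius_px <= 0:
        raise ValueError("link_radius_px must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    tracks: list[FocusTrack] = []
    open_tracks: list[FocusTrack] = []
    for frame, foci in enumerate(per_frame_foci):
        dets = [tuple(float(v) for v in f.centroid[-2:]) for f in foci]
        vals = (
            intensities[frame]
            if intensities is not None
            else [None] * len(dets)
        )
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.entries[-1]
            if frame - last.frame - 1 > max_gap:
                continue
            for di, d in enumerate(dets):
                dist = math.hypot(last.centroid[0] - d[0], last.centroid[1] - d[1])
                if dist <= link_radius_px:
                    candidates.append((dist, ti, di))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            tr = open_tracks[ti]
            gap = frame - tr.entries[-1].frame - 1
            if gap > 0:
                tr.gap_frames.extend(range(tr.entries[-1].frame + 1, frame))
            tr.entries.append(TrackEntry(frame, dets[di], vals[di]))
            used_tracks.add(ti)
            used_dets.add(di)
        for di, d in enumerate(dets):
            if di not in used_dets:
                tr = FocusTrack(track_id=len(tracks))
                tr.entries.append(TrackEntry(frame, d, vals[di]))
                tracks.append(tr)
                open_tracks.append(tr)
        open_tracks = [
            tr for tr in open_tracks if frame - tr.entries[-1].frame <= max_gap
        ]
    return tracks


def annotate_track_sites(track: FocusTrack, site_radius_px: float = 3.0) -> FocusTrack:
    """Compute modal site, site persistence and relocation count in place.

    Detections are clustered into sites greedily (a detection joins the
    nearest existing site within ``site_radius_px``, else founds a new one;
    site centres are running means). The modal site is the most-visited
    cluster; persistence is the fraction of the track's spanned frames with
    a detection within ``site_radius_px`` of the modal centre. A relocation
    is a consecutive pair of linked detections more than ``site_radius_px``
    apart. Single-entry tracks have persistence 1.0 by convention.
    """
    pts = np.array([e.centroid for e in track.entries], dtype=float)
    centres: list[np.ndarray] = []
    counts: list[int] = []
    assign: list[int] = []
    for p in pts:
        if centres:
            d = [np.hypot(*(p - c)) for c in centres]
            best = int(np.argmin(d))
        else:
            best = -1
            d = [np.inf]
        if centres and d[best] <= site_radius_px:
            counts[best] += 1
            centres[best] = centres[best] + (p - centres[best]) / counts[best]
            assign.append(best)
        else:
            centres.append(p.copy())
            counts.append(1)
            assign.append(len(centres) - 1)
    modal = int(np.argmax(counts))
    track.modal_site = (float(centres[modal][0]), float(centres[modal][1]))
    within = np.hypot(*(pts - centres[modal]).T) <= site_radius_px
    track.site_persistence = float(within.sum() / track.span_frames)
    jumps = np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1 else np.array([])
    track.n_relocations = int((jumps > site_radius_px).sum())
    return track


def dynamics_summary(
    tracks: list[FocusTrack],
    site_radius_px: float = 3.0,
    static_threshold: float = 0.7,
    min_track_length: int = 2,
) -> dict:
    """Summarise a strain's tracks: static fraction and lifetimes.

    A track is "static" when its site persistence is at least
    ``static_threshold`` — the quantitative counterpart of a white spot in
    the temporal projection. Tracks shorter than ``min_track_length``
    detections are counted but excluded from the static fraction (their
    persistence is 1.0 by construction and carries no information).
    """
    if not tracks:
        raise ValueError("need at least one track")
    for tr in tracks:
        annotate_track_sites(tr, site_radius_px)
    scored = [tr for tr in tracks if tr.lifetime >= min_track_length]
    static = [tr for tr in scored if tr.site_persistence >= static_threshold]
    lifetimes = [tr.lifetime for tr in tracks]
    return {
        "n_tracks": len(tracks),
        "n_scored_tracks": len(scored),
        "n_short_tracks": len(tracks) - len(scored),
        "static_fraction": (len(static) / len(scored)) if scored else float("nan"),
        "median_lifetime_frames": float(np.median(lifetimes)),
        "total_relocations": int(sum(tr.n_relocations or 0 for tr in tracks)),
        "site_radius_px": site_radius_px,
        "static_threshold": static_threshold,
    }
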