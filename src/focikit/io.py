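"""Image-stack and ROI input/output.

The pipeline's canonical in-memory image is a 5-D array ordered
``(time, z, channel, y, x)`` holding 16-bit camera counts, together with the
physical metadata needed downstream (pixel size, z-step, frame interval).
Stacks are stored as TIFF with an ``axes`` tag; files written by other tools
(including OME-TIFF) are accepted as long as their axes string is parseable.

Regions of interest are polygons (or rectangles) drawn around groups of
cells, with an inclusive z-extent; all threshold statistics downstream are
computed per ROI. Pixel coordinates are ``(y, x)``, origin top-left,
0-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "ROI",
    "ROISet",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "select_best_z",
]

#: metadata used when a file carries none (pixel size is an assumption;
#: z-step and frame interval follow the acquisition protocol the synthetic
#: scenes emulate)
DEFAULT_PIXEL_SIZE_UM = 0.065
DEFAULT_Z_STEP_UM = 0.25
DEFAULT_FRAME_INTERVAL_S = 90.0

_AXIS_POSITION = {"T": 0, "Z": 1, "C": 2, "S": 2, "Y": 3, "X": 4}


class FormatError(ValueError):
    """Raised for files whose layout cannot be interpreted."""


@dataclass
class ImageStack:
    """A ``(t, z, c, y, x)`` intensity stack in camera counts.

    Parameters
    ----------
    pixels
        Non-negative intensity array, five dimensions, each of size >= 1.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    z_step_um
        Spacing between z-sections in micrometres.
    frame_interval_s
        Time between frames in seconds (1.0 for static stacks).
    channel_names
        One label per channel; auto-filled as ``ch0, ch1, ...`` if omitted.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    frame_interval_s: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must be 5-D (t, z, c, y, x); got {self.pixels.ndim} dims"
            )
        if any(s < 1 for s in self.pixels.shape):
            raise ValueError(f"all dimensions must be >= 1; got {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        for name in ("pixel_size_um", "z_step_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"channel_names has {len(self.channel_names)} entries for "
                f"{self.n_channels} channels"
            )

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def plane(self, t: int, z: int, channel: int) -> np.ndarray:
        """Return the 2-D plane at the given indices (bounds-checked)."""
        for idx, size, name in (
            (t, self.n_frames, "t"),
            (z, self.n_z, "z"),
            (channel, self.n_channels, "channel"),
        ):
            if not 0 <= idx < size:
                raise IndexError(f"{name}={idx} out of range [0, {size})")
        return self.pixels[t, z, channel]


@dataclass
class ROI:
    """A polygonal region of interest with an inclusive z-extent.

    ``vertices`` are ``(y, x)`` pixel coordinates (>= 3 for a polygon).
    Rectangles are represented as their 4-vertex polygon; use
    :meth:`from_rect` to build one from two corners.
    """

    label: str
    vertices: np.ndarray  # (n, 2) float, rows (y, x)
    z_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (y, x) pairs")
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")
        z_lo, z_hi = self.z_range
        if z_lo > z_hi:
            raise ValueError(f"z_lo={z_lo} > z_hi={z_hi}")

    @classmethod
    def from_rect(
        cls,
        label: str,
        corner_a: tuple[float, float],
        corner_b: tuple[float, float],
        z_range: tuple[int, int] = (0, 0),
    ) -> "ROI":
        """Build a rectangle ROI from two opposite corners (inclusive)."""
        y0, y1 = sorted((corner_a[0], corner_b[0]))
        x0, x1 = sorted((corner_a[1], corner_b[1]))
        verts = [(y0, x0), (y0, x1), (y1, x1), (y1, x0)]
        return cls(label=label, vertices=np.array(verts, dtype=float), z_range=z_range)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean footprint of the polygon on an image of the given shape.

        A pixel belongs to the ROI iff its centre (the integer coordinate)
        is inside the polygon under the even-odd rule; pixel centres lying
        exactly on an edge are included.
        """
        h, w = shape
        ys = self.vertices[:, 0]
        xs = self.vertices[:, 1]
        y_lo = max(int(np.floor(ys.min())), 0)
        y_hi = min(int(np.ceil(ys.max())), h - 1)
        x_lo = max(int(np.floor(xs.min())), 0)
        x_hi = min(int(np.ceil(xs.max())), w - 1)
        mask = np.zeros(shape, dtype=bool)
        if y_hi < y_lo or x_hi < x_lo:
            return mask
        py, px = np.meshgrid(
            np.arange(y_lo, y_hi + 1, dtype=float),
            np.arange(x_lo, x_hi + 1, dtype=float),
            indexing="ij",
        )
        inside = np.zeros(py.shape, dtype=bool)
        boundary = np.zeros(py.shape, dtype=bool)
        n = len(self.vertices)
        for i in range(n):
            y1, x1 = self.vertices[i]
            y2, x2 = self.vertices[(i + 1) % n]
            # even-odd ray crossing (ray towards +x)
            cond = (y1 > py) != (y2 > py)
            with np.errstate(divide="ignore", invalid="ignore"):
                x_cross = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= cond & (px < x_cross)
            # pixel centre exactly on the segment
            seg = np.hypot(y2 - y1, x2 - x1)
            if seg == 0:
                on = (np.abs(py - y1) < 1e-9) & (np.abs(px - x1) < 1e-9)
            else:
                cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
                t = ((py - y1) * (y2 - y1) + (px - x1) * (x2 - x1)) / seg**2
                on = (np.abs(cross) / seg < 1e-9) & (t >= -1e-12) & (t <= 1 + 1e-12)
            boundary |= on
        mask[y_lo : y_hi + 1, x_lo : x_hi + 1] = inside | boundary
        return mask


@dataclass
class ROISet:
    """An ordered collection of ROIs with unique labels."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, label: str) -> ROI:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ROISet):
            return NotImplemented
        if len(self) != len(other):
            return False
        return all(
            a.label == b.label
            and a.z_range == b.z_range
            and np.allclose(a.vertices, b.vertices)
            for a, b in zip(self.rois, other.rois)
        )


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as 16-bit TIFF with axes and physical metadata.

    Raises ``ValueError`` if any intensity exceeds the 16-bit range.
    """
    pixels = np.asarray(stack.pixels)
    if np.any(pixels > 65535):
        raise ValueError("intensities exceed the 16-bit range (max 65535)")
    tifffile.imwrite(
        str(path),
        pixels.astype(np.uint16),
        metadata={
            "axes": "TZCYX",
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "frame_interval_s": stack.frame_interval_s,
            "channel_names": list(stack.channel_names),
        },
    )


def read_stack(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> ImageStack:
    """Read a TIFF / OME-TIFF stack, normalising axes to ``(t, z, c, y, x)``.

    Missing axes become size-1 dimensions. Physical metadata is taken from
    the file when present, otherwise from the keyword defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        meta: dict = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
    if data.ndim != len(axes):  # pragma: no cover - defensive
        raise FormatError(f"axes string {axes!r} does not match {data.ndim}-D data")
    # squeeze unknown size-1 axes, refuse unknown axes that carry data
    keep_axes = ""
    for i, ax in enumerate(axes):
        if ax in _AXIS_POSITION:
            keep_axes += ax
        elif data.shape[i] == 1:
            data = np.squeeze(data, axis=len(keep_axes))
        else:
            raise FormatError(f"cannot interpret axis {ax!r} in axes string {axes!r}")
    if len(set(_AXIS_POSITION[a] for a in keep_axes)) != len(keep_axes):
        raise FormatError(f"duplicate axes in {axes!r}")
    # insert missing axes at their canonical positions
    order = sorted(range(len(keep_axes)), key=lambda i: _AXIS_POSITION[keep_axes[i]])
    data = np.transpose(data, order)
    present = sorted(_AXIS_POSITION[a] for a in keep_axes)
    for pos in range(5):
        if pos not in present:
            data = np.expand_dims(data, axis=pos)
    return ImageStack(
        pixels=data,
        pixel_size_um=float(meta.get("pixel_size_um", pixel_size_um)),
        z_step_um=float(meta.get("z_step_um", z_step_um)),
        frame_interval_s=float(meta.get("frame_interval_s", frame_interval_s)),
        channel_names=list(meta.get("channel_names", [])),
    )


# ---------------------------------------------------------------------------
# ROI I/O
#
# Two equivalent on-disk dialects:
#  * tab-separated, one ROI per line:
#       label <TAB> polygon|rect <TAB> z_lo <TAB> z_hi <TAB> y1,x1;y2,x2;...
#    (a rect record carries its two opposite corners)
#  * JSON: {"rois": [{"label", "type", "vertices", "z_lo", "z_hi"}, ...]}


def write_rois(rois: ROISet, path: str | Path) -> None:
    """Write an ROI set; dialect chosen by extension (.json else TSV)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "rois": [
                {
                    "label": r.label,
                    "type": "polygon",
                    "vertices": [[float(y), float(x)] for y, x in r.vertices],
                    "z_lo": int(r.z_range[0]),
                    "z_hi": int(r.z_range[1]),
                }
                for r in rois
            ]
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    lines = []
    for r in rois:
        verts = ";".join(f"{y:g},{x:g}" for y, x in r.vertices)
        lines.append(
            f"{r.label}\tpolygon\t{r.z_range[0]}\t{r.z_range[1]}\t{verts}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_roi_record(
    label: str, kind: str, z_lo: str, z_hi: str, verts: str, lineno: int
) -> ROI:
    try:
        pairs = [
            tuple(float(v) for v in p.split(","))
            for p in verts.split(";")
            if p.strip()
        ]
        if any(len(p) != 2 for p in pairs):
            raise ValueError("vertex is not a y,x pair")
        z = (int(z_lo), int(z_hi))
        if kind == "polygon":
            return ROI(label=label, vertices=np.array(pairs), z_range=z)
        if kind == "rect":
            if len(pairs) != 2:
                raise ValueError("rect record needs exactly 2 corners")
            return ROI.from_rect(label, pairs[0], pairs[1], z_range=z)
        raise ValueError(f"unknown ROI type {kind!r}")
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_rois(path: str | Path) -> ROISet:
    """Read an ROI set written by :func:`write_rois` (either dialect).

    Rectangle records are expanded to their 4-vertex polygon equivalent so
    a single representation flows through the pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    rois: list[ROI] = []
    if path.suffix.lower() == ".json":
        payload = json.loads(text) if text.strip() else {"rois": []}
        for i, rec in enumerate(payload.get("rois", []), start=1):
            verts = ";".join(f"{y},{x}" for y, x in rec["vertices"])
            rois.append(
                _parse_roi_record(
                    rec["label"],
                    rec.get("type", "polygon"),
                    str(rec.get("z_lo", 0)),
                    str(rec.get("z_hi", 0)),
                    verts,
                    i,
                )
            )
        return ROISet(rois)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 5:
            raise FormatError(f"line {lineno}: expected 5 tab-separated fields")
        rois.append(_parse_roi_record(*parts, lineno))
    return ROISet(rois)


# ---------------------------------------------------------------------------


def select_best_z(stack: ImageStack, channel: int, t: int) -> int:
    """Index of the highest-contrast z-section of one channel at one frame.

    Contrast is the per-slice standard deviation of intensities, which is
    invariant under global additive offsets and equivariant under positive
    scaling, so the selected index does not depend on camera offset or gain.
    Ties break to the lowest index.
    """
    if not 0 <= channel < stack.n_channels:
        raise IndexError(f"channel={channel} out of range [0, {stack.n_channels})")
    if not 0 <= t < stack.n_frames:
        raise IndexError(f"t={t} out of range [0, {stack.n_frames})")
    sds = stack.pixels[t, :, channel].astype(np.float64).std(axis=(1, 2))
    return int(np.argmax(sds))
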