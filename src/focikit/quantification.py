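"""Focus intensity measurement with annulus background subtraction.

Each focus is measured as the mean intensity over its pixel set; the local
background is the mean over a 1-pixel-wide (configurable) annulus obtained
by dilating the object with a 3x3 square element, excluding the object
itself, any other segmented focus, and out-of-image pixels. The corrected
intensity is the difference, which makes the measurement invariant under a
global additive camera offset. Corrected values may be negative under noise
and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import BinaryMask, FocusObject

__all__ = [
    "FocusMeasurement",
    "FrequencyEstimate",
    "measure_focus",
    "annulus_background",
    "quantify_foci",
    "foci_per_cell",
    "measurements_to_frame",
]


class DegenerateAnnulusError(ValueError):
    """The background annulus around a focus contains no usable pixel."""


@dataclass
class FocusMeasurement:
    focus_id: int
    roi_label: str
    area_px: int
    mean_intensity: float
    background_mean: float
    corrected_intensity: float
    centroid: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = self.mean_intensity - self.background_mean
        if not np.isclose(self.corrected_intensity, expected, rtol=0, atol=1e-9):
            raise ValueError("corrected_intensity must equal mean - background")


@dataclass
class FrequencyEstimate:
    """Foci-per-cell ratio for one strain / image set."""

    strain_label: str
    n_foci: int
    n_cells: int
    foci_per_cell: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.foci_per_cell != self.n_foci / self.n_cells:
            raise ValueError("foci_per_cell must equal n_foci / n_cells exactly")


def measure_focus(plane: np.ndarray, focus: FocusObject) -> float:
    """Arithmetic mean intensity over the focus pixel set."""
    if len(focus.pixel_set) == 0:
        raise ValueError("focus has an empty pixel set")
    coords = tuple(focus.pixel_set.T)
    return float(np.asarray(plane, dtype=np.float64)[coords].mean())


def _focus_mask(plane_shape: tuple[int, ...], focus: FocusObject) -> np.ndarray:
    m = np.zeros(plane_shape, dtype=bool)
    m[tuple(focus.pixel_set.T)] = True
    return m


def annulus_background(
    plane: np.ndarray,
    focus: FocusObject,
    all_foci_mask: np.ndarray | BinaryMask | None = None,
    width_px: int = 1,
) -> float:
    """Mean intensity of the annulus of ``width_px`` pixels around a focus.

    The annulus is the dilation of the focus by a square 3x3 element
    (applied ``width_px`` times) minus the focus itself, minus pixels
    belonging to any other segmented focus, clipped to the image bounds.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    plane = np.asarray(plane)
    obj = _focus_mask(plane.shape, focus)
    structure = np.ones((3,) * plane.ndim, dtype=bool)
    dilated = ndi.binary_dilation(obj, structure=structure, iterations=width_px)
    annulus = dilated & ~obj
    if all_foci_mask is not None:
        other = all_foci_mask.mask if isinstance(all_foci_mask, BinaryMask) else all_foci_mask
        # drop annulus pixels claimed by any *other* focus
        annulus &= ~(np.asarray(other, dtype=bool) & ~obj)
    if not annulus.any():
        raise DegenerateAnnulusError(
            f"focus {focus.id} in ROI {focus.roi_label!r} has an empty annulus"
        )
    return float(plane[annulus].astype(np.float64).mean())


def quantify_foci(
    plane: np.ndarray,
    foci: list[FocusObject],
    all_foci_mask: np.ndarray | BinaryMask | None = None,
    width_px: int = 1,
) -> list[FocusMeasurement]:
    """Measure every focus; output ordered by focus id.

    If ``all_foci_mask`` is omitted it is built from the foci themselves so
    neighbouring objects are always excluded from each other's annuli.
    """
    plane = np.asarray(plane)
    if all_foci_mask is None and foci:
        m = np.zeros(plane.shape, dtype=bool)
        for f in foci:
            m[tuple(f.pixel_set.T)] = True
        all_foci_mask = m
    out = []
    for f in sorted(foci, key=lambda f: f.id):
        mean = measure_focus(plane, f)
        bg = annulus_background(plane, f, all_foci_mask, width_px=width_px)
        out.append(
            FocusMeasurement(
                focus_id=f.id,
                roi_label=f.roi_label,
                area_px=f.area_px,
                mean_intensity=mean,
                background_mean=bg,
                corrected_intensity=mean - bg,
                centroid=f.centroid,
            )
        )
    return out


def foci_per_cell(n_foci: int, n_cells: int, strain_label: str = "") -> FrequencyEstimate:
    """Exact foci-per-cell ratio; cell counts are supplied (manual counting)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1 (division by zero otherwise)")
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    return FrequencyEstimate(
        strain_label=strain_label,
        n_foci=n_foci,
        n_cells=n_cells,
        foci_per_cell=n_foci / n_cells,
    )


def measurements_to_frame(measurements: list[FocusMeasurement]) -> pd.DataFrame:
    """Tabulate measurements for CSV export."""
    rows = []
    for m in measurements:
        row = {
            "roi_label": m.roi_label,
            "focus_id": m.focus_id,
            "area_px": m.area_px,
            "mean_intensity": m.mean_intensity,
            "background_mean": m.background_mean,
            "corrected_intensity": m.corrected_intensity,
        }
        if len(m.centroid) == 3:
            row["centroid_z"] = m.centroid[0]
            row["centroid_y"] = m.centroid[1]
            row["centroid_x"] = m.centroid[2]
        else:
            row["centroid_y"] = m.centroid[0]
            row["centroid_x"] = m.centroid[1]
        rows.append(row)
    columns = [
        "roi_label",
        "focus_id",
        "area_px",
        "mean_intensity",
        "background_mean",
        "corrected_intensity",
        "centroid_y",
        "centroid_x",
    ]
    if any(len(m.centroid) == 3 for m in measurements):
        columns.append("centroid_z")
    return pd.DataFrame(rows, columns=columns if rows else columns)
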