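"""Focus segmentation by ROI-wise SD thresholding.

A pixel inside an ROI is classified "focus" when its intensity exceeds the
ROI mean by more than ``k_sd`` standard deviations (population SD over all
ROI pixels); connected components of the resulting binary mask that are
larger than ``min_size_px`` pixels (strictly) become focus objects. Defaults
``k_sd = 2.2`` and ``min_size_px = 6`` follow the published detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io import ROI, ROISet, ImageStack, select_best_z

__all__ = [
    "SegmentationParams",
    "BinaryMask",
    "FocusObject",
    "threshold_roi",
    "extract_foci",
    "segment_foci",
]


class DegenerateROIError(ValueError):
    """ROI too small for the threshold statistics to be defined."""


@dataclass(frozen=True)
class SegmentationParams:
    """Detection parameters.

    k_sd
        Threshold multiplier: focus pixels satisfy
        ``I > mean_ROI + k_sd * SD_ROI`` (strict).
    min_size_px
        Components must be strictly larger than this many pixels.
    connectivity
        4 or 8 in 2-D, 6 or 26 in 3-D.
    exclude_boundary_foci
        Drop foci touching the ROI footprint boundary (off by default; the
        detection rule has no edge exclusion).
    """

    k_sd: float = 2.2
    min_size_px: int = 6
    connectivity: int = 8
    exclude_boundary_foci: bool = False

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.min_size_px < 0:
            raise ValueError("min_size_px must be >= 0")
        if self.connectivity not in (4, 8, 6, 26):
            raise ValueError("connectivity must be one of 4, 8 (2-D) or 6, 26 (3-D)")

    def structure(self, ndim: int) -> np.ndarray:
        """scipy.ndimage connectivity structure for the configured setting."""
        if ndim == 2:
            return ndi.generate_binary_structure(2, 2 if self.connectivity == 8 else 1)
        if ndim == 3:
            return ndi.generate_binary_structure(3, 3 if self.connectivity == 26 else 1)
        raise ValueError(f"unsupported dimensionality {ndim}")


@dataclass
class BinaryMask:
    """Focus/not-focus classification of one ROI's footprint."""

    mask: np.ndarray  # bool, congruent with the analysed plane or volume
    roi_label: str
    footprint: np.ndarray  # bool, the ROI's rasterised extent

    def __post_init__(self) -> None:
        if self.mask.shape != self.footprint.shape:
            raise ValueError("mask and footprint shapes differ")
        if np.any(self.mask & ~self.footprint):
            raise ValueError("mask has true pixels outside the ROI footprint")


@dataclass
class FocusObject:
    """One segmented connected component."""

    id: int
    roi_label: str
    pixel_set: np.ndarray  # (n, 2) or (n, 3) int coordinates, raster order
    area_px: int
    centroid: tuple[float, ...]  # (y, x) or (z, y, x)

    def __post_init__(self) -> None:
        if self.area_px != len(self.pixel_set):
            raise ValueError("area_px must equal |pixel_set|")


def threshold_roi(
    plane: np.ndarray, roi: ROI, params: SegmentationParams | None = None
) -> BinaryMask:
    """Threshold one ROI of an intensity plane (or volume in 3-D mode).

    The mask is true exactly where the pixel lies in the ROI footprint and
    its intensity strictly exceeds ``mean + k_sd * SD``, both statistics
    taken over every ROI pixel (population SD). A uniform ROI therefore
    yields an empty mask.
    """
    params = params or SegmentationParams()
    plane = np.asarray(plane)
    if plane.ndim == 2:
        footprint = roi.rasterize(plane.shape)
    elif plane.ndim == 3:
        footprint2d = roi.rasterize(plane.shape[1:])
        footprint = np.broadcast_to(footprint2d, plane.shape).copy()
    else:
        raise ValueError("plane must be 2-D or 3-D")
    n = int(footprint.sum())
    if n < 2:
        raise DegenerateROIError(
            f"ROI {roi.label!r} covers {n} pixel(s); threshold statistics undefined"
        )
    values = plane[footprint].astype(np.float64)
    mean = values.mean()
    sd = values.std()  # population SD, divisor N
    mask = np.zeros(plane.shape, dtype=bool)
    mask[footprint] = values > mean + params.k_sd * sd
    return BinaryMask(mask=mask, roi_label=roi.label, footprint=footprint)


def extract_foci(
    mask: BinaryMask, params: SegmentationParams | None = None
) -> list[FocusObject]:
    """Connected components of a binary mask, size-filtered into foci.

    Components with area <= ``min_size_px`` are discarded (the rule is
    strictly "larger than"). Ids are assigned in raster order of each
    component's first pixel, so output is deterministic.
    """
    params = params or SegmentationParams()
    structure = params.structure(mask.mask.ndim)
    labels, n_comp = ndi.label(mask.mask, structure=structure)
    foci: list[FocusObject] = []
    if n_comp == 0:
        return foci
    if params.exclude_boundary_foci:
        eroded = ndi.binary_erosion(
            mask.footprint, structure=np.ones((3,) * mask.mask.ndim, dtype=bool)
        )
        edge = mask.footprint & ~eroded
        edge_labels = set(np.unique(labels[edge])) - {0}
    else:
        edge_labels = set()
    next_id = 0
    # ndi.label assigns component labels in raster order of first occurrence
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labels == comp)
        if len(coords) <= params.min_size_px or comp in edge_labels:
            continue
        centroid = tuple(float(c) for c in coords.mean(axis=0))
        foci.append(
            FocusObject(
                id=next_id,
                roi_label=mask.roi_label,
                pixel_set=coords,
                area_px=len(coords),
                centroid=centroid,
            )
        )
        next_id += 1
    return foci


def segment_foci(
    stack: ImageStack,
    rois: ROISet,
    channel: int = 0,
    t: int = 0,
    params: SegmentationParams | None = None,
    mode: str = "2d",
    z: int | None = None,
) -> list[FocusObject]:
    """Segment foci in every ROI of one frame of a stack.

    In 2-D mode (default) the analysis plane is the highest-contrast
    z-section of the requested channel (or the explicit ``z``); in 3-D mode
    each ROI's inclusive z-range is thresholded as a volume and components
    are extracted under the volumetric connectivity. Focus ids are unique
    across the returned list.
    """
    params = params or SegmentationParams()
    out: list[FocusObject] = []
    offset = 0
    if mode == "2d":
        z_sel = select_best_z(stack, channel, t) if z is None else z
        plane = stack.plane(t, z_sel, channel)
        for roi in rois:
            mask = threshold_roi(plane, roi, params)
            foci = extract_foci(mask, params)
            for f in foci:
                f.id += offset
            offset += len(foci)
            out.extend(foci)
    elif mode == "3d":
        vol_params = params
        if params.connectivity in (4, 8):
            vol_params = SegmentationParams(
                k_sd=params.k_sd,
                min_size_px=params.min_size_px,
                connectivity=26 if params.connectivity == 8 else 6,
                exclude_boundary_foci=params.exclude_boundary_foci,
            )
        for roi in rois:
            z_lo, z_hi = roi.z_range
            if not (0 <= z_lo <= z_hi < stack.n_z):
                raise IndexError(
                    f"ROI {roi.label!r} z-range {roi.z_range} outside stack z-extent"
                )
            volume = stack.pixels[t, z_lo : z_hi + 1, channel]
            mask = threshold_roi(volume, roi, vol_params)
            foci = extract_foci(mask, vol_params)
            for f in foci:
                f.id += offset
                # report centroid z in absolute stack coordinates
                zc, yc, xc = f.centroid
                f.centroid = (zc + z_lo, yc, xc)
                f.pixel_set = f.pixel_set + np.array([z_lo, 0, 0])
            offset += len(foci)
            out.extend(foci)
    else:
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    return out
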