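"""Channel pre-processing and ROI extraction.

A fluorescence image of a double-stained neutrophil sample carries two
channels: a total-DNA channel (cell-permeable dye, e.g. Hoechst 33342)
showing all DNA, and an extracellular-DNA channel (cell-impermeable dye,
e.g. SYTOX Green) showing only DNA reachable from outside an intact
plasma membrane.  Regions of interest (ROIs) are connected components of
above-threshold pixels on one channel; they are the unit every later
stage (feature extraction, scoring, classification) operates on.

Intensities are kept in native camera units throughout: thresholds and
class feature ranges are tuned per laboratory, so no bit-depth
normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage

from .errors import ParameterError, StructuralError

ChannelRole = Literal["total_dna", "extracellular_dna"]

#: 4- and 8-neighbour structuring elements for connected components.
_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class ChannelImage:
    """One 2D intensity raster tagged with its channel role.

    Parameters
    ----------
    pixels:
        2D array of non-negative intensities in native camera units.
    channel_role:
        ``"total_dna"`` or ``"extracellular_dna"``.
    source_id:
        Identifier of the originating image file (used in reports).
    """

    pixels: np.ndarray
    channel_role: ChannelRole
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise StructuralError(
                f"channel image must be a non-empty 2D raster, got shape {px.shape}"
            )
        if np.any(px < 0):
            raise StructuralError("channel image contains negative intensities")
        if self.channel_role not in ("total_dna", "extracellular_dna"):
            raise ParameterError(f"unknown channel role {self.channel_role!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FilterSpec:
    """Optional smoothing filter applied before segmentation.

    ``kind`` is ``"none"``, ``"gaussian"`` (with ``sigma`` > 0 in pixels)
    or ``"median"`` (with odd-sized square window of half-width
    ``radius`` >= 1, i.e. a (2r+1) x (2r+1) footprint).
    """

    kind: Literal["none", "gaussian", "median"] = "none"
    sigma: float = 1.0
    radius: int = 1

    def __post_init__(self) -> None:
        if self.kind == "gaussian" and not self.sigma > 0:
            raise ParameterError(f"gaussian sigma must be > 0, got {self.sigma}")
        if self.kind == "median" and (self.radius < 1 or int(self.radius) != self.radius):
            raise ParameterError(f"median radius must be an integer >= 1, got {self.radius}")
        if self.kind not in ("none", "gaussian", "median"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")


@dataclass(frozen=True)
class SegmentationParams:
    """Per-channel thresholding parameters.

    A pixel is foreground when its intensity is strictly greater than
    ``threshold``; components smaller than ``min_roi_area`` pixels are
    discarded as noise.
    """

    threshold: float = 0.0
    min_roi_area: int = 4
    connectivity: int = 8
    filter: FilterSpec = field(default_factory=FilterSpec)

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ParameterError(f"threshold must be >= 0, got {self.threshold}")
        if self.min_roi_area < 1:
            raise ParameterError(f"min_roi_area must be >= 1, got {self.min_roi_area}")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")


@dataclass(frozen=True)
class ROI:
    """A connected pixel region on one channel.

    ``pixel_set`` stores (row, col) coordinates; ``bounding_box`` is the
    tight box in 0-based half-open convention
    ``(row_min, col_min, row_max, col_max)``.
    """

    roi_id: int
    channel_role: ChannelRole
    pixel_set: frozenset[tuple[int, int]]
    bounding_box: tuple[int, int, int, int]

    @property
    def area(self) -> int:
        return len(self.pixel_set)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """ROI pixels as (rows, cols) index arrays."""
        rc = np.array(sorted(self.pixel_set), dtype=np.intp)
        return rc[:, 0], rc[:, 1]

    @staticmethod
    def from_mask(mask: np.ndarray, roi_id: int, channel_role: ChannelRole) -> "ROI":
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise StructuralError("cannot build an ROI from an empty mask")
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        return ROI(
            roi_id=roi_id,
            channel_role=channel_role,
            pixel_set=frozenset(zip(rows.tolist(), cols.tolist())),
            bounding_box=bbox,
        )


def apply_filter(img: ChannelImage, filter_spec: FilterSpec) -> ChannelImage:
    """Smooth a channel; ``kind="none"`` returns the input unchanged."""
    if filter_spec.kind == "none":
        return img
    px = img.pixels.astype(np.float64)
    if filter_spec.kind == "gaussian":
        out = ndimage.gaussian_filter(px, sigma=filter_spec.sigma)
    else:  # median
        size = 2 * int(filter_spec.radius) + 1
        out = ndimage.median_filter(px, size=size)
    return ChannelImage(pixels=out, channel_role=img.channel_role, source_id=img.source_id)


def threshold_segment(img: ChannelImage, params: SegmentationParams) -> list[ROI]:
    """Segment one channel into ROIs.

    Foreground pixels are those with intensity strictly above
    ``params.threshold``; maximal connected components (under the
    configured connectivity) of at least ``params.min_roi_area`` pixels
    become ROIs, numbered 1..n in scan order.  The optional smoothing
    filter is applied first.
    """
    filtered = apply_filter(img, params.filter)
    fg = filtered.pixels > params.threshold
    labels, n = ndimage.label(fg, structure=_STRUCTURES[params.connectivity])
    rois: list[ROI] = []
    rid = 0
    for lab in range(1, n + 1):
        mask = labels == lab
        if int(mask.sum()) < params.min_roi_area:
            continue
        rid += 1
        rois.append(ROI.from_mask(mask, roi_id=rid, channel_role=img.channel_role))
    return rois


def label_map(rois: Iterable[ROI], shape: tuple[int, int]) -> np.ndarray:
    """Render ROIs as a 16-bit label map (0 = background, k = roi_id k)."""
    out = np.zeros(shape, dtype=np.uint16)
    for roi in rois:
        r, c = roi.coords()
        out[r, c] = roi.roi_id
    return out
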