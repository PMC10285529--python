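"""Per-ROI feature vectors.

Five features drive the classification of NETosis stages: ROI area,
mean brightness in the total-DNA channel, mean and standard deviation
of brightness in the extracellular-DNA channel, and the mean
Laplacian-of-Gaussian (LoG) response of the total-DNA channel.  Two
circularity measures (area/perimeter^2 and area/diameter^2) are
computed as optional extras; they are excluded from the default class
definitions because neither separates polymorphonuclear cells from the
other stages — elongated but regular nuclei score as circular as discs.

All statistics are taken over an ROI's own pixel set, never its
bounding box, and regardless of which channel the ROI was segmented on:
``mean_total`` and ``mean_log`` always read the total-DNA raster under
the footprint, ``mean_extra``/``std_extra`` the extracellular raster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import ParameterError, StructuralError
from .segment import ChannelImage, ROI

#: Feature names usable in class definitions, in export order.
FEATURE_NAMES = (
    "area",
    "mean_total",
    "mean_extra",
    "std_extra",
    "mean_log",
    "circ_perimeter",
    "circ_diameter",
)


@dataclass(frozen=True)
class LoGParams:
    """Scale of the Laplacian-of-Gaussian response.

    The response is the Laplacian of the Gaussian-smoothed image.  With
    this sign convention a bright compact blob gives a strongly negative
    central response, while a diffuse clump with blurred borders — the
    hallmark of bacterial aggregates — gives a response of small
    magnitude.  ``sigma`` defaults to 2 px, roughly the edge width of a
    focused cell at low magnification.
    """

    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"LoG sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class FeatureVector:
    area: int
    mean_total: float
    mean_extra: float
    std_extra: float
    mean_log: float
    circ_perimeter: float
    circ_diameter: float  # NaN for single-pixel ROIs (zero diameter)

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def log_response(total_img: ChannelImage, log_params: LoGParams) -> np.ndarray:
    """LoG response raster of the total-DNA channel (a.u. / px^2).

    Computed as the discrete 5-point Laplacian of the Gaussian-smoothed
    image rather than by convolution with a sampled LoG kernel: the
    discrete Laplacian has an exactly zero response to constant and
    affine rasters, which a truncated LoG kernel only approximates.
    """
    smoothed = ndimage.gaussian_filter(
        total_img.pixels.astype(np.float64), sigma=log_params.sigma
    )
    return ndimage.laplace(smoothed)


def compute_features(
    roi: ROI,
    total_img: ChannelImage,
    extra_img: ChannelImage,
    log_params: LoGParams = LoGParams(),
    log_raster: np.ndarray | None = None,
) -> FeatureVector:
    """Compute the feature vector of one ROI.

    ``log_raster`` may carry a precomputed :func:`log_response` so the
    (whole-image) LoG convolution is shared between the ROIs of one
    image.  Standard deviations use the population (n-denominator)
    form: the features describe the ROI itself, not a sample from it.
    """
    if total_img.shape != extra_img.shape:
        raise StructuralError(
            f"channel shapes differ: {total_img.shape} vs {extra_img.shape}"
        )
    h, w = total_img.shape
    r0, c0, r1, c1 = roi.bounding_box
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise StructuralError(f"ROI {roi.roi_id} lies outside the {h}x{w} image")
    rows, cols = roi.coords()
    if log_raster is None:
        log_raster = log_response(total_img, log_params)
    total_px = total_img.pixels[rows, cols].astype(np.float64)
    extra_px = extra_img.pixels[rows, cols].astype(np.float64)
    circ_p, circ_d = compute_circularity(roi)
    return FeatureVector(
        area=roi.area,
        mean_total=float(total_px.mean()),
        mean_extra=float(extra_px.mean()),
        std_extra=float(extra_px.std()),  # population SD
        mean_log=float(log_raster[rows, cols].mean()),
        circ_perimeter=circ_p,
        circ_diameter=circ_d,
    )


def _perimeter_edge_count(roi: ROI) -> int:
    # Count pixel edges bordering background (4-neighbourhood).
    r0, c0, r1, c1 = roi.bounding_box
    mask = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    rows, cols = roi.coords()
    mask[rows - r0 + 1, cols - c0 + 1] = True
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int((mask & ~np.roll(mask, shift, axis=(0, 1))).sum())
    return edges


def _diameter(roi: ROI) -> float:
    # Maximal pairwise pixel-centre distance; convex hull keeps this
    # tractable for large ROIs.
    pts = np.array(sorted(roi.pixel_set), dtype=np.float64)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear point sets
            pass
    return float(pdist(pts).max())


def compute_circularity(roi: ROI) -> tuple[float, float]:
    """Return ``(area/perimeter^2, area/diameter^2)``.

    The perimeter is the count of pixel edges bordering background; the
    diameter is the maximal distance between pixel centres.  A
    single-pixel ROI has zero diameter and yields ``nan`` for the
    diameter ratio.
    """
    area = roi.area
    perim = _perimeter_edge_count(roi)
    diam = _diameter(roi)
    circ_p = area / perim**2
    circ_d = area / diam**2 if diam > 0 else math.nan
    return circ_p, circ_d
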