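"""Synthetic two-channel fixture images with per-object ground truth.

The generator renders the object morphologies seen in double-stained
neutrophil preparations so that every other module can be exercised
without real microscopy data:

* **PMN** — small, lobulated (union of overlapping ellipses), moderate
  total-DNA brightness, no extracellular signal;
* **RND** — disc-shaped, the brightest class in the total-DNA channel
  (decondensed chromatin binds more dye);
* **RUP** — larger, dimmer, cloud-like, still membrane-intact;
* **PER** — cell-sized with extracellular-dye signal over its footprint
  (permeabilized plasma membrane);
* **NET** — large region in the extracellular channel with spatially
  heterogeneous brightness (a low-frequency multiplicative field with a
  guaranteed SD floor);
* **EXTRA_ARTIFACT** — smooth near-uniform extracellular patch, the
  kind produced by uneven background illumination;
* **BACTERIA** — diffuse low-intensity clump with strongly blurred
  borders, hence a mean LoG response of small magnitude.

Intensity targets are *measured* means over the object's mask eroded by
one pixel (soft anti-aliased edges excluded): each object's amplitude
map is rescaled after shaping/blurring so that this interior mean hits
a value drawn from the configured range.  All randomness comes from one
seeded generator, so a scene is bit-reproducible from its seed.

What this emulates — and what it does not: objects sit on a flat or
smoothly-tilted background with i.i.d. Gaussian camera noise; there is
no point-spread-function optics model, no out-of-focus light, no
vignetting, and no touching/merged cells unless overlap is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import NetquantError, UsageError


class PlacementError(NetquantError):
    """Objects could not be placed without overlap at the requested density."""


ShapeKind = str  # {lobulated, disc, cloud, diffuse_clump, smooth_patch}

BACKGROUND_LEVEL = 100.0  # a.u., 16-bit native units
NOISE_SD = 5.0


@dataclass(frozen=True)
class ObjectSpec:
    """How to render the objects of one class in a scene.

    ``mean_total_range`` / ``mean_extra_range`` are *measured* interior
    means (background included) in a.u.; ``area_range`` is the mask
    pixel count.  ``edge_sigma`` blurs the painted amplitude map —
    small for focused cells, large for the border-less bacterial
    clumps.  ``heterogeneity`` is the relative SD of the multiplicative
    brightness field used for NETs.
    """

    class_name: str
    count: int
    area_range: tuple[int, int]
    mean_total_range: tuple[float, float] = (0.0, 0.0)
    mean_extra_range: tuple[float, float] = (0.0, 0.0)
    intra_object_noise_sd: float = 0.0
    shape: ShapeKind = "disc"
    edge_sigma: float = 0.5
    heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise UsageError(f"{self.class_name}: count must be >= 0")
        for name, (lo, hi) in (("area_range", self.area_range),
                               ("mean_total_range", self.mean_total_range),
                               ("mean_extra_range", self.mean_extra_range)):
            if lo > hi:
                raise UsageError(f"{self.class_name}: invalid {name} ({lo}, {hi})")


#: Rendering presets for the seven named classes.  Intensities are in
#: native 16-bit units on a background of 100 a.u.; they were chosen to
#: reproduce the ordinal relations between classes (RND brightest, RUP
#: larger and dimmer than PMN, bacteria dimmest and most diffuse, NETs
#: far larger than any cell) at separations a well-tuned experiment
#: would show.
CLASS_PRESETS: Mapping[str, ObjectSpec] = {
    "PMN": ObjectSpec("PMN", 0, (80, 200), (1000, 1700), (0, 0), 30, "lobulated", 0.5),
    "RND": ObjectSpec("RND", 0, (100, 260), (2700, 3900), (0, 0), 40, "disc", 0.5),
    "RUP": ObjectSpec("RUP", 0, (380, 800), (520, 800), (0, 0), 25, "cloud", 0.7),
    "PER": ObjectSpec("PER", 0, (80, 200), (1000, 1700), (700, 1400), 30, "lobulated", 0.5),
    "NET": ObjectSpec("NET", 0, (1200, 2500), (0, 0), (750, 1150), 0, "cloud", 1.0,
                      heterogeneity=0.40),
    "EXTRA_ARTIFACT": ObjectSpec("EXTRA_ARTIFACT", 0, (1500, 3000), (0, 0), (420, 650),
                                 0, "smooth_patch", 1.2),
    "BACTERIA": ObjectSpec("BACTERIA", 0, (500, 1100), (200, 310), (0, 0), 10,
                           "diffuse_clump", 3.0),
}

#: Faint sub-threshold total-DNA haze painted under NETs (chromatin is
#: mostly extracellular, so the total channel shows little).
NET_TOTAL_HAZE = 20.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic two-channel scene."""

    shape: tuple[int, int] = (256, 256)
    objects: tuple[ObjectSpec, ...] = ()
    background_level: float = BACKGROUND_LEVEL
    background_gradient: float = 0.0  # peak-to-centre amplitude, extracellular channel
    noise_sd: float = NOISE_SD
    overlap_allowed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 64 or self.shape[1] < 64:
            raise UsageError(f"scene must be at least 64x64, got {self.shape}")


@dataclass(frozen=True)
class SynthObject:
    label: str
    pixel_mask: np.ndarray  # full-image bool raster
    bounding_box: tuple[int, int, int, int]  # half-open

    @property
    def area(self) -> int:
        return int(self.pixel_mask.sum())


@dataclass(frozen=True)
class GroundTruth:
    objects: tuple[SynthObject, ...]
    class_counts: Mapping[str, int]
    total_net_area: int


# ---------------------------------------------------------------------------
# Shape synthesis (local boolean canvases)
# ---------------------------------------------------------------------------

def _disc_mask(radius: float) -> np.ndarray:
    n = int(math.ceil(2 * radius)) + 3
    yy, xx = np.mgrid[:n, :n] - (n - 1) / 2.0
    return yy**2 + xx**2 <= radius**2


def _ellipse_mask(a: float, b: float, angle: float, canvas: int) -> np.ndarray:
    yy, xx = np.mgrid[:canvas, :canvas] - (canvas - 1) / 2.0
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _shape_mask(kind: ShapeKind, target_area: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of roughly ``target_area`` pixels on a tight canvas."""
    r0 = math.sqrt(target_area / math.pi)
    if kind == "disc":
        mask = _disc_mask(r0)
    elif kind == "smooth_patch":
        ecc = rng.uniform(1.1, 1.7)
        a, b = r0 * math.sqrt(ecc), r0 / math.sqrt(ecc)
        canvas = int(2 * max(a, b)) + 5
        mask = _ellipse_mask(a, b, rng.uniform(0, math.pi), canvas)
    elif kind == "lobulated":
        n_lobes = int(rng.integers(2, 5))
        canvas = int(4 * r0) + 7
        mask = np.zeros((canvas, canvas), dtype=bool)
        lobe_r = r0 / math.sqrt(n_lobes) * 1.15
        centre = (canvas - 1) / 2.0
        for _ in range(n_lobes):
            off = rng.uniform(-0.9, 0.9, size=2) * lobe_r
            a = lobe_r * rng.uniform(0.8, 1.4)
            b = lobe_r**2 / a
            sub = _ellipse_mask(a, b, rng.uniform(0, math.pi), canvas)
            shift = np.round(off).astype(int)
            mask |= np.roll(sub, shift, axis=(0, 1))
        mask = ndimage.binary_closing(mask, iterations=1)
    elif kind == "cloud":
        canvas = int(3.2 * r0) + 7
        yy, xx = np.mgrid[:canvas, :canvas] - (canvas - 1) / 2.0
        theta = np.arctan2(yy, xx)
        rr = np.hypot(yy, xx)
        bound = np.ones_like(theta) * r0
        for k in range(2, 6):
            amp = rng.uniform(0, 0.22 / math.sqrt(k - 1))
            bound += r0 * amp * np.sin(k * theta + rng.uniform(0, 2 * math.pi))
        mask = rr <= bound
    elif kind == "diffuse_clump":
        canvas = int(3.4 * r0) + 9
        mask = np.zeros((canvas, canvas), dtype=bool)
        centre = (canvas - 1) / 2.0
        n_spots = max(6, int(target_area / 40))
        for _ in range(n_spots):
            pos = centre + rng.normal(scale=r0 * 0.55, size=2)
            rad = rng.uniform(2.0, 4.5)
            yy, xx = np.mgrid[:canvas, :canvas]
            mask |= (yy - pos[0]) ** 2 + (xx - pos[1]) ** 2 <= rad**2
        mask = ndimage.binary_closing(mask, iterations=2)
        lab, n = ndimage.label(mask)
        if n > 1:  # keep the dominant component connected
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    else:
        raise UsageError(f"unknown shape kind {kind!r}")
    return _fit_area(mask, target_area)


def _fit_area(mask: np.ndarray, target_area: float) -> np.ndarray:
    """Nudge a mask's area toward the target by dilation/erosion."""
    for _ in range(6):
        area = int(mask.sum())
        if abs(area - target_area) / target_area < 0.12:
            break
        if area < target_area:
            mask = np.pad(mask, 1)
            mask = ndimage.binary_dilation(mask)
        else:
            eroded = ndimage.binary_erosion(mask)
            if not eroded.any():
                break
            mask = eroded
    return _crop_to_content(mask)


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return mask[r0:r1 + 1, c0:c1 + 1]


# ---------------------------------------------------------------------------
# Amplitude painting
# ---------------------------------------------------------------------------

def _interior(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return eroded if eroded.any() else mask


def _paint(
    mask: np.ndarray,
    target_mean: float,
    edge_sigma: float,
    intra_sd: float,
    heterogeneity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Float amplitude map whose interior mean equals ``target_mean``.

    The map is shaped (heterogeneity field, intra-object noise, edge
    blur) first, then rescaled so its mean over the 1-px-eroded mask
    hits the target exactly; camera noise added later by the scene
    renderer is the only remaining variability.
    """
    amp = mask.astype(np.float64) * target_mean
    if heterogeneity > 0:
        # low-frequency multiplicative field, clipped so the dimmest
        # NET region keeps >= 50% of the base brightness (no internal
        # fragmentation at segmentation time) while preserving the SD
        # floor that separates NETs from smooth artifacts
        g = ndimage.gaussian_filter(rng.normal(size=mask.shape), sigma=6.0)
        sd = g[mask].std()
        if sd > 0:
            g = np.clip(g / sd, -1.25, 2.0)
            amp = amp * (1.0 + heterogeneity * g)
    if intra_sd > 0:
        amp = amp + mask * rng.normal(scale=intra_sd, size=mask.shape)
    if edge_sigma > 0:
        amp = ndimage.gaussian_filter(amp, sigma=edge_sigma)
    interior = _interior(mask)
    current = float(amp[interior].mean())
    if current <= 0:
        current = 1.0
    return amp * (target_mean / current)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _place(
    canvas_shape: tuple[int, int],
    obj_shape: tuple[int, int],
    occupied: list[tuple[int, int, int, int]],
    overlap_allowed: bool,
    rng: np.random.Generator,
    pad: int = 5,
    max_tries: int = 300,
) -> tuple[int, int]:
    h, w = canvas_shape
    oh, ow = obj_shape
    if oh + 6 >= h or ow + 6 >= w:
        raise PlacementError(f"object {obj_shape} too large for scene {canvas_shape}")
    for _ in range(max_tries):
        r = int(rng.integers(3, h - oh - 3))
        c = int(rng.integers(3, w - ow - 3))
        box = (r - pad, c - pad, r + oh + pad, c + ow + pad)
        if overlap_allowed or not any(
            box[0] < b[2] and b[0] < box[2] and box[1] < b[3] and b[1] < box[3]
            for b in occupied
        ):
            occupied.append(box)
            return r, c
    raise PlacementError(
        f"could not place a {obj_shape} object after {max_tries} tries; "
        "reduce object counts or enable overlap"
    )


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a scene into (total raster, extracellular raster, truth).

    Deterministic for a fixed ``spec.seed``; rasters are uint16 in
    native units.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    total = np.zeros((h, w), dtype=np.float64)
    extra = np.zeros((h, w), dtype=np.float64)
    occupied: list[tuple[int, int, int, int]] = []
    objects: list[SynthObject] = []
    bg = spec.background_level

    # place big objects (NETs, artifacts, clumps) first: small cells fit
    # into the remaining gaps far more reliably than the reverse order
    instances = [o for o in spec.objects for _ in range(o.count)]
    instances.sort(key=lambda o: -(o.area_range[0] + o.area_range[1]))
    def draw(lo_hi: tuple[float, float]) -> float:
        lo_, hi_ = lo_hi
        return float(rng.uniform(lo_ + 0.1 * (hi_ - lo_), hi_ - 0.1 * (hi_ - lo_)))

    for ospec in instances:
        lo, hi = ospec.area_range
        target_area = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        mask = _shape_mask(ospec.shape, target_area, rng)
        r, c = _place((h, w), mask.shape, occupied, spec.overlap_allowed, rng)
        mh, mw = mask.shape

        if ospec.mean_total_range[1] > 0:
            amp = _paint(mask, draw(ospec.mean_total_range) - bg,
                         ospec.edge_sigma, ospec.intra_object_noise_sd, 0.0, rng)
            total[r:r + mh, c:c + mw] += amp
        if ospec.mean_extra_range[1] > 0:
            amp = _paint(mask, draw(ospec.mean_extra_range) - bg,
                         ospec.edge_sigma, ospec.intra_object_noise_sd,
                         ospec.heterogeneity, rng)
            extra[r:r + mh, c:c + mw] += amp
        if ospec.class_name == "NET":
            total[r:r + mh, c:c + mw] += ndimage.gaussian_filter(
                mask * NET_TOTAL_HAZE, sigma=1.5
            )

        full_mask = np.zeros((h, w), dtype=bool)
        full_mask[r:r + mh, c:c + mw] = mask
        rows, cols = np.nonzero(full_mask)
        bbox = (int(rows.min()), int(cols.min()),
                int(rows.max()) + 1, int(cols.max()) + 1)
        objects.append(SynthObject(ospec.class_name, full_mask, bbox))

    total += bg
    extra += bg
    if spec.background_gradient != 0:
        yy, xx = np.mgrid[:h, :w]
        ramp = (yy / (h - 1) - 0.5) + 0.6 * np.sin(2 * math.pi * xx / w)
        extra += spec.background_gradient * ramp / np.abs(ramp).max()
    if spec.noise_sd > 0:
        total += rng.normal(scale=spec.noise_sd, size=(h, w))
        extra += rng.normal(scale=spec.noise_sd, size=(h, w))

    counts: dict[str, int] = {}
    for obj in objects:
        counts[obj.label] = counts.get(obj.label, 0) + 1
    truth = GroundTruth(
        objects=tuple(objects),
        class_counts=counts,
        total_net_area=sum(o.area for o in objects if o.label == "NET"),
    )
    to_u16 = lambda a: np.clip(np.rint(a), 0, 65535).astype(np.uint16)
    return to_u16(total), to_u16(extra), truth


# ---------------------------------------------------------------------------
# Presets and fixture emission
# ---------------------------------------------------------------------------

PRESETS = ("clean_separation", "uneven_background", "benchmark4class", "mixed_coculture")

#: Per-preset object count ranges (inclusive), drawn per image.
_PRESET_COUNTS: Mapping[str, Mapping[str, tuple[int, int]]] = {
    "clean_separation": {"PMN": (4, 7), "RND": (2, 4), "RUP": (2, 3),
                         "PER": (2, 4), "NET": (1, 2)},
    "uneven_background": {"PMN": (3, 5), "PER": (1, 2), "NET": (1, 2),
                          "EXTRA_ARTIFACT": (1, 3)},
    "benchmark4class": {"PMN": (4, 7), "RUP": (2, 3), "PER": (2, 4), "NET": (1, 2)},
    "mixed_coculture": {"PMN": (3, 5), "RND": (1, 3), "RUP": (1, 3), "PER": (1, 3),
                        "NET": (1, 1), "BACTERIA": (1, 2), "EXTRA_ARTIFACT": (0, 1)},
}


def preset_scene(name: str, seed: int, shape: tuple[int, int] = (256, 256)) -> SceneSpec:
    """Build the scene specification of a named preset for one seed."""
    if name not in PRESETS:
        raise UsageError(f"unknown preset {name!r}; choose from {PRESETS}")
    rng = np.random.default_rng(seed)
    objs = []
    for cls, (lo, hi) in _PRESET_COUNTS[name].items():
        count = int(rng.integers(lo, hi + 1))
        objs.append(replace(CLASS_PRESETS[cls], count=count))
    gradient = 30.0 if name == "uneven_background" else 0.0
    return SceneSpec(shape=shape, objects=tuple(objs),
                     background_gradient=gradient, seed=seed)


def preset_config(name: str):
    """Pipeline configuration whose ranges bracket a preset's distributions.

    The class [l, u] intervals are deliberately wider than the
    generator's drawing ranges (segmentation includes dimmer
    anti-aliased edge pixels, which pull measured means below the
    interior targets) while staying pairwise separable on at least one
    feature per class pair.
    """
    from .config import parse_config

    if name not in PRESETS:
        raise UsageError(f"unknown preset {name!r}; choose from {PRESETS}")
    classes = {
        "PMN": {"area": [50, 280], "mean_total": [750, 2000], "mean_extra": [0, 280]},
        "RND": {"area": [70, 360], "mean_total": [2300, 4300], "mean_extra": [0, 280]},
        "RUP": {"area": [300, 1000], "mean_total": [380, 950], "mean_extra": [0, 280]},
        "PER": {"area": [50, 280], "mean_total": [750, 2000], "mean_extra": [500, 1800]},
        "BACTERIA": {"area": [350, 1500], "mean_total": [130, 330],
                     "mean_extra": [0, 280], "mean_log": [-8, 8]},
    }
    if name == "benchmark4class":  # the 4-class benchmark mode
        classes = {k: classes[k] for k in ("PMN", "RUP", "PER")}
    data = {
        "s": 0.2,
        "assign_threshold": 0.8,
        "reject_threshold": 0.4,
        "log_sigma": 2.0,
        "segmentation": {
            "total_dna": {"threshold": 150, "min_roi_area": 4, "connectivity": 8},
            "extracellular_dna": {"threshold": 300, "min_roi_area": 4, "connectivity": 8},
        },
        "stage1": {
            "min_net_area": 600,
            "net_mean_range": [330, "inf"],
            "net_std_range": [150, "inf"],
            "mode": "hard",
        },
        "mask": {"overlap_fraction_threshold": 0.5},
        "classes": classes,
    }
    return parse_config(data)


def emit_fixture_set(
    preset: str,
    out_dir: str | Path,
    seed: int,
    n_images: int = 10,
    shape: tuple[int, int] = (256, 256),
) -> dict[str, list[Path]]:
    """Write a fixture set: TIFFs, VOC truth XMLs, truth CSV, config.

    Image ``i`` uses scene seed ``seed * 100003 + i`` (kept well below
    2**31 for small seeds), recorded in the truth CSV.
    """
    from .config import dump_config
    from .io import write_two_channel_tiff, write_voc_annotations

    if preset not in PRESETS:
        raise UsageError(f"unknown preset {preset!r}; choose from {PRESETS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiffs: list[Path] = []
    xmls: list[Path] = []
    rows: list[dict] = []
    for i in range(n_images):
        scene_seed = (seed * 100003 + i) % (2**31 - 1)
        spec = preset_scene(preset, scene_seed, shape)
        total, extra, truth = render_scene(spec)
        stem = f"{preset}_{i:03d}"
        tiff_path = out_dir / f"{stem}.tiff"
        xml_path = out_dir / f"{stem}.xml"
        write_two_channel_tiff(tiff_path, total, extra)
        write_voc_annotations(
            xml_path,
            [(o.label, o.bounding_box) for o in truth.objects],
            image_name=tiff_path.name,
            image_shape=shape,
        )
        for k, obj in enumerate(truth.objects):
            r0, c0, r1, c1 = obj.bounding_box
            rows.append({
                "source_id": tiff_path.name, "object_id": k, "label": obj.label,
                "area": obj.area, "bbox_row_min": r0, "bbox_col_min": c0,
                "bbox_row_max": r1, "bbox_col_max": c1, "scene_seed": scene_seed,
            })
        tiffs.append(tiff_path)
        xmls.append(xml_path)
    truth_csv = out_dir / "truth.csv"
    pd.DataFrame(rows).to_csv(truth_csv, index=False)
    config_path = out_dir / "config.yaml"
    dump_config(preset_config(preset), config_path)
    return {"tiffs": tiffs, "xmls": xmls, "truth_csv": [truth_csv],
            "config": [config_path]}
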