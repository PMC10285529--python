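"""File input/output: TIFF channels, label maps, VOC annotations.

Input images are TIFFs holding at least two channels (as pages or as a
leading/trailing axis); by convention channel 0 is the total-DNA stain
and channel 1 the extracellular-DNA stain, remappable via
``channel_order``.  Two single-channel files may be supplied instead.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from lxml import etree

from .errors import InputError, StructuralError
from .segment import ChannelImage


def _split_channels(arr: np.ndarray, path: Path) -> tuple[np.ndarray, np.ndarray]:
    if arr.ndim == 2:
        raise InputError(f"{path}: expected a two-channel image, found a single 2D page")
    if arr.ndim != 3:
        raise InputError(f"{path}: unsupported TIFF layout with shape {arr.shape}")
    # channel axis is whichever axis has length >= 2 and is much smaller
    # than the spatial axes; prefer the leading axis (multi-page TIFF)
    if arr.shape[0] <= 8:
        return arr[0], arr[1]
    if arr.shape[2] <= 8:
        return arr[..., 0], arr[..., 1]
    raise InputError(f"{path}: cannot locate a channel axis in shape {arr.shape}")


def read_two_channel_tiff(
    path: str | Path,
    channel_order: Sequence[int] = (0, 1),
) -> tuple[ChannelImage, ChannelImage]:
    """Read a two-channel TIFF as (total-DNA, extracellular-DNA) images.

    ``channel_order`` maps (total, extracellular) to channel indices in
    the file, e.g. ``(1, 0)`` when the stains are stored swapped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    c0, c1 = _split_channels(np.asarray(arr), path)
    channels = {0: c0, 1: c1}
    total = channels[channel_order[0]]
    extra = channels[channel_order[1]]
    if total.shape != extra.shape:
        raise InputError(f"{path}: channel shapes differ: {total.shape} vs {extra.shape}")
    return (
        ChannelImage(total, "total_dna", source_id=path.name),
        ChannelImage(extra, "extracellular_dna", source_id=path.name),
    )


def write_two_channel_tiff(
    path: str | Path, total: np.ndarray, extra: np.ndarray
) -> None:
    """Write a 2-page TIFF: page 0 total-DNA, page 1 extracellular-DNA."""
    stack = np.stack([np.asarray(total), np.asarray(extra)])
    tifffile.imwrite(Path(path), stack)


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit TIFF (0 = background, k = ROI k)."""
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.uint16))


# ---------------------------------------------------------------------------
# Pascal-VOC-style bounding-box annotations
# ---------------------------------------------------------------------------

def read_voc_annotations(path: str | Path) -> list[tuple[str, tuple[int, int, int, int]]]:
    """Read (label, box) pairs from a Pascal-VOC XML annotation file.

    VOC stores 1-based inclusive pixel coordinates (xmin, ymin, xmax,
    ymax).  They are converted to the internal 0-based half-open
    (row_min, col_min, row_max, col_max) convention by ``(min-1, max)``
    so box areas equal pixel counts.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    tree = etree.parse(str(path))
    out: list[tuple[str, tuple[int, int, int, int]]] = []
    for obj in tree.findall(".//object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise StructuralError(f"{path}: malformed <object> element")
        xmin = int(float(bnd.findtext("xmin")))
        ymin = int(float(bnd.findtext("ymin")))
        xmax = int(float(bnd.findtext("xmax")))
        ymax = int(float(bnd.findtext("ymax")))
        out.append((name, (ymin - 1, xmin - 1, ymax, xmax)))
    return out


def write_voc_annotations(
    path: str | Path,
    boxes: Sequence[tuple[str, tuple[int, int, int, int]]],
    image_name: str = "",
    image_shape: tuple[int, int] | None = None,
) -> None:
    """Write (label, half-open box) pairs as a Pascal-VOC XML file."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = image_name
    if image_shape is not None:
        size = etree.SubElement(root, "size")
        etree.SubElement(size, "height").text = str(image_shape[0])
        etree.SubElement(size, "width").text = str(image_shape[1])
        etree.SubElement(size, "depth").text = "2"
    for label, (r0, c0, r1, c1) in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = label
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(c0 + 1)
        etree.SubElement(bnd, "ymin").text = str(r0 + 1)
        etree.SubElement(bnd, "xmax").text = str(c1)
        etree.SubElement(bnd, "ymax").text = str(r1)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))
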