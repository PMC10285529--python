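"""Shared fixtures and brute-force oracles.

The oracles here (flood fill, exhaustive box matching) deliberately do
not reuse any package code path they are meant to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from netquant.segment import ChannelImage


@pytest.fixture
def make_image():
    def _make(pixels, role="total_dna", source_id="test"):
        return ChannelImage(np.asarray(pixels, dtype=np.float64), role, source_id)

    return _make


# ---------------------------------------------------------------------------
# Flood-fill oracle for connected components
# ---------------------------------------------------------------------------

def flood_fill_components(
    raster: np.ndarray, threshold: float, connectivity: int
) -> list[frozenset[tuple[int, int]]]:
    """Connected components of strictly-above-threshold pixels via an
    explicit stack-based flood fill."""
    h, w = raster.shape
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if seen[r, c] or raster[r, c] <= threshold:
                continue
            stack = [(r, c)]
            seen[r, c] = True
            comp = set()
            while stack:
                rr, cc = stack.pop()
                comp.add((rr, cc))
                for dr, dc in nbrs:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and not seen[nr, nc] \
                            and raster[nr, nc] > threshold:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            comps.append(frozenset(comp))
    return comps


# ---------------------------------------------------------------------------
# Exhaustive one-to-one matching oracle
# ---------------------------------------------------------------------------

def _iou_plain(a, b) -> float:
    ih = min(a[2], b[2]) - max(a[0], b[0])
    iw = min(a[3], b[3]) - max(a[1], b[1])
    if ih <= 0 or iw <= 0:
        return 0.0
    inter = ih * iw
    area = lambda x: (x[2] - x[0]) * (x[3] - x[1])
    return inter / (area(a) + area(b) - inter)


def best_matching_oracle(preds, truths, threshold=0.10):
    """Lexicographically best sorted-descending IoU sequence over all
    one-to-one matchings of eligible pairs, by exhaustive enumeration."""
    eligible = [
        (i, j, _iou_plain(p, t))
        for i, p in enumerate(preds)
        for j, t in enumerate(truths)
        if _iou_plain(p, t) >= threshold
    ]
    best: tuple = ()

    def extend(chosen, used_p, used_t, start):
        nonlocal best
        seq = tuple(sorted((v for _, _, v in chosen), reverse=True))
        if seq > best:
            best = seq
        for k in range(start, len(eligible)):
            i, j, v = eligible[k]
            if i in used_p or j in used_t:
                continue
            extend(chosen + [eligible[k]], used_p | {i}, used_t | {j}, k + 1)

    extend([], set(), set(), 0)
    return best


def random_boxes(rng: np.random.Generator, n: int, size: int = 20):
    boxes = []
    for _ in range(n):
        r0 = int(rng.integers(0, size - 2))
        c0 = int(rng.integers(0, size - 2))
        r1 = int(rng.integers(r0 + 1, size))
        c1 = int(rng.integers(c0 + 1, size))
        boxes.append((r0, c0, r1, c1))
    return boxes
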