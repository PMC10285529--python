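"""Evaluation against ground-truth bounding boxes.

Predicted and manually annotated objects are matched one-to-one by
greedily pairing the globally highest-IoU (intersection over union of
bounding boxes) remaining pair while the IoU stays at or above a
threshold, 0.10 by default — a permissive value suited to NET
quantification, where predicted and hand-drawn boxes of the same
diffuse object can differ substantially.  The matches populate a
confusion matrix whose rows are predicted classes plus Unknown, whose
columns are truth classes, and which carries Unmatched margins on both
sides; per-class precision and recall follow directly, with the
Unknown and Unmatched rows excluded from precision and the Unmatched
column from recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import StructuralError

Box = tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open

UNKNOWN = "Unknown"
UNMATCHED = "Unmatched"


def _box_area(b: Box) -> int:
    return (b[2] - b[0]) * (b[3] - b[1])


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    for box in (a, b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise StructuralError(f"degenerate bounding box {box}")
    inter_h = min(a[2], b[2]) - max(a[0], b[0])
    inter_w = min(a[3], b[3]) - max(a[1], b[1])
    if inter_h <= 0 or inter_w <= 0:
        return 0.0
    inter = inter_h * inter_w
    union = _box_area(a) + _box_area(b) - inter
    return inter / union


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.iou_threshold <= 1:
            raise StructuralError(
                f"iou_threshold must be in (0,1], got {self.iou_threshold}"
            )


def match_boxes(
    preds: Sequence[Box],
    truths: Sequence[Box],
    config: MatchConfig = MatchConfig(),
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one matching of prediction and truth boxes.

    Repeatedly selects the unmatched (pred, truth) pair with the
    globally highest IoU >= threshold.  Ties are broken by smaller
    prediction index, then smaller truth index, making reports
    deterministic.  Returns ``(pred_index, truth_index, iou)`` triples.
    """
    candidates = []
    for i, p in enumerate(preds):
        for j, t in enumerate(truths):
            v = iou(p, t)
            if v >= config.iou_threshold:
                candidates.append((-v, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for neg_v, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j, -neg_v))
    return pairs


@dataclass(frozen=True)
class MatchReport:
    """Confusion matrix with unmatched margins plus per-class statistics.

    ``confusion`` rows: predicted labels (+ Unknown + Unmatched);
    columns: truth labels (+ Unmatched).  ``precision``/``recall`` map
    named classes to ratios; ``avg_precision``/``avg_recall`` are
    unweighted means over the named classes.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_preds: tuple[int, ...]
    unmatched_truths: tuple[int, ...]
    confusion: pd.DataFrame
    precision: Mapping[str, float]
    recall: Mapping[str, float]
    avg_precision: float
    avg_recall: float

    def to_text(self) -> str:
        """Human-readable report, statistics rounded to 2 decimals."""
        lines = ["Confusion matrix (rows = predicted, columns = ground truth):",
                 self.confusion.to_string()]
        lines.append("")
        for c in self.precision:
            lines.append(
                f"{c}: precision {self.precision[c]:.2f}, recall {self.recall[c]:.2f}"
            )
        lines.append(f"Average precision: {100 * self.avg_precision:.0f}%")
        lines.append(f"Average recall: {100 * self.avg_recall:.0f}%")
        return "\n".join(lines)


def confusion_and_stats(
    pairs: Sequence[tuple[int, int, float]],
    pred_labels: Sequence[str],
    truth_labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> MatchReport:
    """Build the confusion matrix and per-class precision/recall.

    Matched pairs count in cell (predicted label, truth label);
    unmatched predictions fall in the Unmatched column of their label's
    row, unmatched truths in the Unmatched row of their class's column.
    Precision(c) = diagonal / row total over named-class rows only;
    recall(c) = diagonal / column total.  Averages are unweighted means
    over the named classes present in the truth/prediction label sets.
    """
    if class_order is None:
        seen: list[str] = []
        for lab in list(truth_labels) + [l for l in pred_labels if l != UNKNOWN]:
            if lab not in seen and lab != UNKNOWN:
                seen.append(lab)
        class_order = seen
    rows = list(class_order) + [UNKNOWN, UNMATCHED]
    cols = list(class_order) + [UNMATCHED]
    confusion = pd.DataFrame(0, index=rows, columns=cols, dtype=int)

    matched_p = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    for i, j, _ in pairs:
        confusion.loc[pred_labels[i], truth_labels[j]] += 1
    unmatched_preds = tuple(i for i in range(len(pred_labels)) if i not in matched_p)
    unmatched_truths = tuple(j for j in range(len(truth_labels)) if j not in matched_t)
    for i in unmatched_preds:
        confusion.loc[pred_labels[i], UNMATCHED] += 1
    for j in unmatched_truths:
        confusion.loc[UNMATCHED, truth_labels[j]] += 1

    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for c in class_order:
        row_total = int(confusion.loc[c].sum())
        col_total = int(confusion[c].sum())
        diag = int(confusion.loc[c, c])
        precision[c] = diag / row_total if row_total else float("nan")
        recall[c] = diag / col_total if col_total else float("nan")
    vals_p = [v for v in precision.values() if not np.isnan(v)]
    vals_r = [v for v in recall.values() if not np.isnan(v)]
    return MatchReport(
        pairs=tuple(pairs),
        unmatched_preds=unmatched_preds,
        unmatched_truths=unmatched_truths,
        confusion=confusion,
        precision=precision,
        recall=recall,
        avg_precision=float(np.mean(vals_p)) if vals_p else float("nan"),
        avg_recall=float(np.mean(vals_r)) if vals_r else float("nan"),
    )


def evaluate_boxes(
    preds: Sequence[tuple[str, Box]],
    truths: Sequence[tuple[str, Box]],
    config: MatchConfig = MatchConfig(),
    class_order: Sequence[str] | None = None,
) -> MatchReport:
    """Match labelled prediction boxes against labelled truth boxes."""
    pairs = match_boxes([b for _, b in preds], [b for _, b in truths], config)
    return confusion_and_stats(
        pairs, [l for l, _ in preds], [l for l, _ in truths], class_order
    )


# ---------------------------------------------------------------------------
# Standalone evaluation from files
# ---------------------------------------------------------------------------

def predictions_from_roi_table(
    table: pd.DataFrame,
    drop_labels: Sequence[str] = ("IGNORED_MASKED", "SKIPPED_SMALL"),
    unknown_labels: Sequence[str] = ("UNKNOWN_INTRACELLULAR", "UNKNOWN_EXTRACELLULAR"),
) -> dict[str, list[tuple[str, Box]]]:
    """Convert a per-ROI table into labelled prediction boxes per image.

    Masked-out and skipped-small ROIs are not reported objects and are
    dropped; both unknown flavours collapse to the ``Unknown`` row.
    """
    out: dict[str, list[tuple[str, Box]]] = {}
    for _, row in table.iterrows():
        label = row["label"]
        if label in drop_labels:
            continue
        if label in unknown_labels:
            label = UNKNOWN
        box = (int(row["bbox_row_min"]), int(row["bbox_col_min"]),
               int(row["bbox_row_max"]), int(row["bbox_col_max"]))
        out.setdefault(str(row["source_id"]), []).append((label, box))
    return out


def evaluate_files(
    pred_csv: str | Path,
    truth_dir: str | Path,
    config: MatchConfig = MatchConfig(),
    class_order: Sequence[str] | None = None,
) -> MatchReport:
    """Evaluate a per-ROI prediction CSV against a directory of VOC XMLs.

    Truth XML files are matched to images by stem: predictions with
    ``source_id`` 'img_003.tiff' read annotations from 'img_003.xml'.
    """
    from .io import read_voc_annotations

    table = pd.read_csv(pred_csv)
    by_image = predictions_from_roi_table(table)
    truth_dir = Path(truth_dir)
    all_pairs: list[tuple[int, int, float]] = []
    pred_labels: list[str] = []
    truth_labels: list[str] = []
    for source_id in sorted(by_image):
        preds = by_image[source_id]
        xml = truth_dir / (Path(source_id).stem + ".xml")
        truths = read_voc_annotations(xml) if xml.exists() else []
        p_off, t_off = len(pred_labels), len(truth_labels)
        pairs = match_boxes([b for _, b in preds], [b for _, b in truths], config)
        all_pairs.extend((i + p_off, j + t_off, v) for i, j, v in pairs)
        pred_labels.extend(l for l, _ in preds)
        truth_labels.extend(l for l, _ in truths)
    return confusion_and_stats(all_pairs, pred_labels, truth_labels, class_order)
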