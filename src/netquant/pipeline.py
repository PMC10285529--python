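"""Two-stage classification workflow, per-image summaries, batch mode.

Per image the workflow is: optional filtering, thresholding + connected
components on both channels, feature extraction, then two
classification stages.  Stage 1 looks only at the extracellular-DNA
channel: components smaller than ``min_net_area`` (typically neutrophils
with a permeabilized membrane, counted later through the total-DNA
channel) are skipped; a sufficiently large component whose mean
brightness and brightness SD fall inside user-defined ranges is a NET —
spatially heterogeneous brightness is what separates real chromatin
clouds from smooth background artifacts — and anything else is flagged
an extracellular artifact for manual inspection.  Stage 2 classifies
total-DNA-channel ROIs with the fuzzy interval scores, after discarding
ROIs lying mostly under the mask of NETs and artifacts, where the
permeabilization status of a cell cannot be judged reliably.

Each image gets a quality score ``Q = 100 * (1 - U / S)`` percent,
where ``U`` is the pixel area of unclassified ROIs and ``S`` the area
of all retained ROIs; areas rather than counts make Q robust to small
artifacts.  A low Q flags images needing parameter re-tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, UsageError
from .features import FeatureVector, LoGParams, compute_features, log_response
from .scoring import (
    AmbiguityReason,
    ClassificationOutcome,
    ClassifierConfig,
    FeatureRange,
    INTRACELLULAR_CLASSES,
    UNKNOWN_EXTRACELLULAR,
    UNKNOWN_INTRACELLULAR,
    partial_score,
)
from .segment import ChannelImage, ROI, SegmentationParams, label_map, threshold_segment

logger = logging.getLogger("netquant")

#: Stage-1 labels (extracellular channel).
NET = "NET"
EXTRA_ARTIFACT = "EXTRA_ARTIFACT"
SKIPPED_SMALL = "SKIPPED_SMALL"
IGNORED_MASKED = "IGNORED_MASKED"

#: Labels that appear in per-image count tables, in report order.
COUNT_LABELS = (
    "PMN",
    "RND",
    "RUP",
    "PER",
    "BACTERIA",
    NET,
    EXTRA_ARTIFACT,
    UNKNOWN_INTRACELLULAR,
    UNKNOWN_EXTRACELLULAR,
    IGNORED_MASKED,
    SKIPPED_SMALL,
)


@dataclass(frozen=True)
class Stage1Params:
    """Hard-interval NET test on the extracellular channel.

    ``mode="soft"`` replaces the hard interval tests with the product of
    the two partial scores at margin factor ``s`` against the assignment
    threshold; it is provided for symmetry with stage 2 but off by
    default.
    """

    min_net_area: int = 600
    net_mean_range: tuple[float, float] = (0.0, float("inf"))
    net_std_range: tuple[float, float] = (0.0, float("inf"))
    mode: Literal["hard", "soft"] = "hard"

    def __post_init__(self) -> None:
        if self.min_net_area < 1:
            raise ConfigError(f"min_net_area must be >= 1, got {self.min_net_area}")
        for name, (l, u) in (("net_mean_range", self.net_mean_range),
                             ("net_std_range", self.net_std_range)):
            if l > u:
                raise ConfigError(f"{name}: lower bound {l} exceeds upper bound {u}")
        if self.mode not in ("hard", "soft"):
            raise ConfigError(f"stage-1 mode must be 'hard' or 'soft', got {self.mode!r}")


@dataclass(frozen=True)
class MaskPolicy:
    """When to ignore a total-DNA ROI lying under the NET/artifact mask.

    An ROI is ignored when the fraction of its pixels inside the mask
    exceeds ``overlap_fraction_threshold``; 0 means any overlap ignores.
    """

    overlap_fraction_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction_threshold <= 1:
            raise ConfigError(
                f"overlap fraction must be in [0,1], got {self.overlap_fraction_threshold}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to process an image end to end."""

    segmentation_total: SegmentationParams = field(default_factory=SegmentationParams)
    segmentation_extra: SegmentationParams = field(default_factory=SegmentationParams)
    stage1: Stage1Params = field(default_factory=Stage1Params)
    mask_policy: MaskPolicy = field(default_factory=MaskPolicy)
    classifier: ClassifierConfig = None  # type: ignore[assignment]
    log_params: LoGParams = field(default_factory=LoGParams)
    candidate_classes: tuple[str, ...] = INTRACELLULAR_CLASSES
    #: Whether extracellular-artifact area counts as unclassified in Q.
    quality_includes_artifacts: bool = True

    def __post_init__(self) -> None:
        if self.classifier is None:
            raise ConfigError("a classifier configuration is required")


@dataclass(frozen=True)
class ImageSummary:
    source_id: str
    counts: Mapping[str, int]
    net_area_fraction: float  # percent of image area covered by NET pixels
    quality_score: float  # Q, percent
    unclassified_area: int  # U
    total_roi_area: int  # S

    def as_row(self) -> dict:
        row: dict = {"source_id": self.source_id}
        row.update({f"n_{k}": self.counts.get(k, 0) for k in COUNT_LABELS})
        row["net_area_percent"] = self.net_area_fraction
        row["quality_score"] = self.quality_score
        return row


def stage1_classify_extracellular(
    rois: Sequence[ROI],
    features: Mapping[int, FeatureVector],
    params: Stage1Params,
    s: float = 0.0,
    assign_threshold: float = 0.8,
) -> dict[int, str]:
    """Label each extracellular-channel ROI NET / EXTRA_ARTIFACT / SKIPPED_SMALL."""
    labels: dict[int, str] = {}
    mean_rng = FeatureRange("mean_extra", *params.net_mean_range)
    std_rng = FeatureRange("std_extra", *params.net_std_range)
    for roi in rois:
        fv = features[roi.roi_id]
        if roi.area < params.min_net_area:
            labels[roi.roi_id] = SKIPPED_SMALL
            continue
        if params.mode == "hard":
            is_net = (
                params.net_mean_range[0] <= fv.mean_extra <= params.net_mean_range[1]
                and params.net_std_range[0] <= fv.std_extra <= params.net_std_range[1]
            )
        else:
            score = partial_score(fv.mean_extra, mean_rng, s) * partial_score(
                fv.std_extra, std_rng, s
            )
            is_net = score >= assign_threshold
        labels[roi.roi_id] = NET if is_net else EXTRA_ARTIFACT
    return labels


def build_mask(
    stage1_labels: Mapping[int, str], rois: Sequence[ROI], shape: tuple[int, int]
) -> np.ndarray:
    """Union of the pixel sets of all NET and artifact ROIs."""
    mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        if stage1_labels.get(roi.roi_id) in (NET, EXTRA_ARTIFACT):
            r, c = roi.coords()
            mask[r, c] = True
    return mask


def stage2_classify_intracellular(
    rois: Sequence[ROI],
    features: Mapping[int, FeatureVector],
    mask: np.ndarray,
    policy: MaskPolicy,
    classifier: ClassifierConfig,
    candidate_classes: Sequence[str] = INTRACELLULAR_CLASSES,
) -> dict[int, ClassificationOutcome]:
    """Score-classify total-DNA-channel ROIs, skipping mask-covered ones."""
    outcomes: dict[int, ClassificationOutcome] = {}
    from .scoring import classify  # local import avoids a cycle in docs builds

    for roi in rois:
        r, c = roi.coords()
        overlap = float(mask[r, c].mean())
        if overlap > policy.overlap_fraction_threshold:
            outcomes[roi.roi_id] = ClassificationOutcome(
                roi.roi_id, {}, IGNORED_MASKED, AmbiguityReason.NONE
            )
            continue
        outcomes[roi.roi_id] = classify(
            features[roi.roi_id],
            classifier,
            candidate_classes,
            roi_id=roi.roi_id,
            unknown_label=UNKNOWN_INTRACELLULAR,
        )
    return outcomes


def quality_score(
    outcomes: Mapping[int, ClassificationOutcome],
    stage1_labels: Mapping[int, str],
    intracellular_rois: Sequence[ROI],
    extracellular_rois: Sequence[ROI],
    include_artifacts: bool = True,
) -> tuple[float, int, int]:
    """Return ``(Q, U, S)``.

    U sums the areas of unknown intracellular ROIs (plus extracellular
    artifacts unless disabled); S sums the areas of all retained ROIs on
    both channels.  Masked-out and skipped-small ROIs enter neither.
    Q is defined as 100 when no ROI was retained at all.
    """
    u = 0
    s_total = 0
    for roi in intracellular_rois:
        label = outcomes[roi.roi_id].label
        if label == IGNORED_MASKED:
            continue
        s_total += roi.area
        if label == UNKNOWN_INTRACELLULAR:
            u += roi.area
    for roi in extracellular_rois:
        label = stage1_labels[roi.roi_id]
        if label == SKIPPED_SMALL:
            continue
        s_total += roi.area
        if label == EXTRA_ARTIFACT and include_artifacts:
            u += roi.area
    q = 100.0 if s_total == 0 else 100.0 * (1.0 - u / s_total)
    return q, u, s_total


@dataclass(frozen=True)
class ImageResult:
    """Full per-image output: ROI table, summary, and label maps."""

    summary: ImageSummary
    roi_table: pd.DataFrame
    label_map_total: np.ndarray
    label_map_extra: np.ndarray


def process_image(
    total_img: ChannelImage,
    extra_img: ChannelImage,
    config: PipelineConfig,
) -> ImageResult:
    """Run the full workflow on one two-channel image."""
    if total_img.shape != extra_img.shape:
        raise InputError(
            f"{total_img.source_id}: channel shapes differ "
            f"{total_img.shape} vs {extra_img.shape}"
        )
    rois_total = threshold_segment(total_img, config.segmentation_total)
    rois_extra = threshold_segment(extra_img, config.segmentation_extra)

    log_raster = log_response(total_img, config.log_params)
    feats_total = {
        r.roi_id: compute_features(r, total_img, extra_img, config.log_params, log_raster)
        for r in rois_total
    }
    feats_extra = {
        r.roi_id: compute_features(r, total_img, extra_img, config.log_params, log_raster)
        for r in rois_extra
    }

    stage1 = stage1_classify_extracellular(
        rois_extra,
        feats_extra,
        config.stage1,
        s=config.classifier.s,
        assign_threshold=config.classifier.assign_threshold,
    )
    mask = build_mask(stage1, rois_extra, extra_img.shape)
    outcomes = stage2_classify_intracellular(
        rois_total, feats_total, mask, config.mask_policy, config.classifier,
        config.candidate_classes,
    )
    q, u, s_total = quality_score(
        outcomes, stage1, rois_total, rois_extra,
        include_artifacts=config.quality_includes_artifacts,
    )

    counts = {k: 0 for k in COUNT_LABELS}
    for oc in outcomes.values():
        counts[oc.label] = counts.get(oc.label, 0) + 1
    for label in stage1.values():
        counts[label] = counts.get(label, 0) + 1
    net_area = sum(r.area for r in rois_extra if stage1[r.roi_id] == NET)
    net_frac = 100.0 * net_area / total_img.pixels.size

    rows = []
    for roi in rois_total:
        oc = outcomes[roi.roi_id]
        fv = feats_total[roi.roi_id]
        rows.append(_roi_row(total_img.source_id, "total_dna", roi, fv, oc.label,
                             oc.ambiguity_reason.value))
    for roi in rois_extra:
        fv = feats_extra[roi.roi_id]
        rows.append(_roi_row(total_img.source_id, "extracellular_dna", roi, fv,
                             stage1[roi.roi_id], "none"))
    roi_table = pd.DataFrame(rows, columns=_ROI_COLUMNS)

    summary = ImageSummary(
        source_id=total_img.source_id,
        counts=counts,
        net_area_fraction=net_frac,
        quality_score=q,
        unclassified_area=u,
        total_roi_area=s_total,
    )
    return ImageResult(
        summary=summary,
        roi_table=roi_table,
        label_map_total=label_map(rois_total, total_img.shape),
        label_map_extra=label_map(rois_extra, extra_img.shape),
    )


_ROI_COLUMNS = [
    "source_id", "channel", "roi_id", "label", "ambiguity_reason",
    "area", "mean_total", "mean_extra", "std_extra", "mean_log",
    "circ_perimeter", "circ_diameter",
    "bbox_row_min", "bbox_col_min", "bbox_row_max", "bbox_col_max",
]


def _roi_row(source_id: str, channel: str, roi: ROI, fv: FeatureVector,
             label: str, reason: str) -> dict:
    r0, c0, r1, c1 = roi.bounding_box
    return {
        "source_id": source_id, "channel": channel, "roi_id": roi.roi_id,
        "label": label, "ambiguity_reason": reason,
        "area": fv.area, "mean_total": fv.mean_total, "mean_extra": fv.mean_extra,
        "std_extra": fv.std_extra, "mean_log": fv.mean_log,
        "circ_perimeter": fv.circ_perimeter, "circ_diameter": fv.circ_diameter,
        "bbox_row_min": r0, "bbox_col_min": c0, "bbox_row_max": r1, "bbox_col_max": c1,
    }


def process_batch(
    images: Iterable[tuple[ChannelImage, ChannelImage] | str | Path],
    config: PipelineConfig,
    out_path: str | Path | None = None,
    per_roi_path: str | Path | None = None,
    quality_alert: float = 50.0,
) -> pd.DataFrame:
    """Process many images; one summary row per image, in input order.

    Items may be ``(total, extra)`` channel pairs or paths to
    two-channel TIFF files.  Images that fail to load are logged and
    skipped rather than aborting the batch.  When ``out_path`` ends in
    ``.xlsx`` an Excel workbook is written (summary + per-ROI sheets);
    otherwise summaries go to CSV.
    """
    from .io import read_two_channel_tiff  # deferred: keeps pipeline importable headless

    items = list(images)
    if not items:
        raise UsageError("process_batch requires at least one image")
    summaries: list[dict] = []
    roi_tables: list[pd.DataFrame] = []
    for item in items:
        try:
            if isinstance(item, (str, Path)):
                total, extra = read_two_channel_tiff(item)
            else:
                total, extra = item
            result = process_image(total, extra, config)
        except Exception as exc:  # noqa: BLE001 — contract: skip, don't abort
            logger.warning("skipping image %s: %s", item, exc)
            summaries.append({"source_id": str(item), "error": str(exc)})
            continue
        row = result.summary.as_row()
        if result.summary.quality_score < quality_alert:
            logger.warning(
                "image %s: quality score %.1f below alert level %.1f",
                result.summary.source_id, result.summary.quality_score, quality_alert,
            )
        logger.info(
            "image %s: %s, Q=%.1f", result.summary.source_id,
            {k: v for k, v in result.summary.counts.items() if v}, row["quality_score"],
        )
        summaries.append(row)
        roi_tables.append(result.roi_table)
    report = pd.DataFrame(summaries)
    if out_path is not None:
        out_path = Path(out_path)
        if out_path.suffix.lower() in (".xlsx", ".xls"):
            with pd.ExcelWriter(out_path) as xw:
                report.to_excel(xw, sheet_name="summary", index=False)
                if roi_tables:
                    pd.concat(roi_tables, ignore_index=True).to_excel(
                        xw, sheet_name="rois", index=False
                    )
        else:
            report.to_csv(out_path, index=False)
    if per_roi_path is not None and roi_tables:
        pd.concat(roi_tables, ignore_index=True).to_csv(per_roi_path, index=False)
    return report
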