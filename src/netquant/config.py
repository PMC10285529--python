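"""YAML configuration for the full pipeline.

One file holds everything: per-channel segmentation parameters, the
stage-1 NET ranges, the mask policy, the LoG scale, and the class
definitions with the shared margin factor ``s`` and decision
thresholds.  Feature ranges are written as two-element lists with
``"inf"`` / ``"-inf"`` sentinels.  No default class ranges are shipped:
intensity scales depend on the microscope, dyes, and exposure of a
particular laboratory, so ranges are tuned per experiment (the
synthetic-fixture generator emits a matching config for its presets).

Example::

    s: 0.2
    assign_threshold: 0.8
    reject_threshold: 0.4
    log_sigma: 2.0
    segmentation:
      total_dna:         {threshold: 150, min_roi_area: 4, connectivity: 8}
      extracellular_dna: {threshold: 300, min_roi_area: 4, connectivity: 8}
    stage1:
      min_net_area: 600
      net_mean_range: [350, inf]
      net_std_range: [90, inf]
    mask:
      overlap_fraction_threshold: 0.5
    classes:
      PMN: {area: [50, 260], mean_total: [800, 1900], mean_extra: [0, 250]}
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .features import LoGParams
from .pipeline import MaskPolicy, PipelineConfig, Stage1Params
from .scoring import (
    ClassDefinition,
    ClassifierConfig,
    FeatureRange,
    INTRACELLULAR_CLASSES,
)
from .segment import FilterSpec, SegmentationParams


def _as_bound(v: Any) -> float:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("inf", "+inf", "infinity"):
            return math.inf
        if s == "-inf":
            return -math.inf
        return float(v)
    return float(v)


def _parse_filter(raw: Mapping[str, Any] | str | None) -> FilterSpec:
    if raw is None or raw == "none":
        return FilterSpec()
    if isinstance(raw, str):
        raise ConfigError(f"filter must be a mapping or 'none', got {raw!r}")
    kind = raw.get("kind", "none")
    return FilterSpec(
        kind=kind,
        sigma=float(raw.get("sigma", 1.0)),
        radius=int(raw.get("radius", 1)),
    )


def _parse_segmentation(raw: Mapping[str, Any]) -> SegmentationParams:
    return SegmentationParams(
        threshold=float(raw.get("threshold", 0.0)),
        min_roi_area=int(raw.get("min_roi_area", 4)),
        connectivity=int(raw.get("connectivity", 8)),
        filter=_parse_filter(raw.get("filter")),
    )


def parse_config(data: Mapping[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML mapping."""
    if "classes" not in data or not data["classes"]:
        raise ConfigError("config must define at least one class under 'classes'")
    classes = {}
    for name, ranges in data["classes"].items():
        frs = tuple(
            FeatureRange(feat, _as_bound(lu[0]), _as_bound(lu[1]))
            for feat, lu in ranges.items()
        )
        classes[name] = ClassDefinition(class_name=name, ranges=frs)
    classifier = ClassifierConfig(
        classes=classes,
        s=float(data.get("s", 0.2)),
        assign_threshold=float(data.get("assign_threshold", 0.8)),
        reject_threshold=float(data.get("reject_threshold", 0.4)),
    )
    seg = data.get("segmentation", {})
    stage1_raw = data.get("stage1", {})
    stage1 = Stage1Params(
        min_net_area=int(stage1_raw.get("min_net_area", 600)),
        net_mean_range=tuple(_as_bound(v) for v in stage1_raw.get("net_mean_range", [0, "inf"])),
        net_std_range=tuple(_as_bound(v) for v in stage1_raw.get("net_std_range", [0, "inf"])),
        mode=stage1_raw.get("mode", "hard"),
    )
    mask_raw = data.get("mask", {})
    candidates = tuple(
        data.get("candidate_classes", [c for c in INTRACELLULAR_CLASSES if c in classes])
    )
    return PipelineConfig(
        segmentation_total=_parse_segmentation(seg.get("total_dna", {})),
        segmentation_extra=_parse_segmentation(seg.get("extracellular_dna", {})),
        stage1=stage1,
        mask_policy=MaskPolicy(float(mask_raw.get("overlap_fraction_threshold", 0.5))),
        classifier=classifier,
        log_params=LoGParams(sigma=float(data.get("log_sigma", 2.0))),
        candidate_classes=candidates,
        quality_includes_artifacts=bool(data.get("quality_includes_artifacts", True)),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return parse_config(data)


def _bound_repr(v: float):
    if math.isinf(v):
        return "inf" if v > 0 else "-inf"
    return v


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a pipeline configuration back to YAML."""
    cls = {
        name: {
            r.feature_name: [_bound_repr(r.l), _bound_repr(r.u)] for r in cd.ranges
        }
        for name, cd in config.classifier.classes.items()
    }

    def seg_dict(p: SegmentationParams) -> dict:
        d: dict[str, Any] = {
            "threshold": p.threshold,
            "min_roi_area": p.min_roi_area,
            "connectivity": p.connectivity,
        }
        if p.filter.kind != "none":
            d["filter"] = {"kind": p.filter.kind, "sigma": p.filter.sigma,
                           "radius": p.filter.radius}
        return d

    data = {
        "s": config.classifier.s,
        "assign_threshold": config.classifier.assign_threshold,
        "reject_threshold": config.classifier.reject_threshold,
        "log_sigma": config.log_params.sigma,
        "segmentation": {
            "total_dna": seg_dict(config.segmentation_total),
            "extracellular_dna": seg_dict(config.segmentation_extra),
        },
        "stage1": {
            "min_net_area": config.stage1.min_net_area,
            "net_mean_range": [_bound_repr(v) for v in config.stage1.net_mean_range],
            "net_std_range": [_bound_repr(v) for v in config.stage1.net_std_range],
            "mode": config.stage1.mode,
        },
        "mask": {"overlap_fraction_threshold": config.mask_policy.overlap_fraction_threshold},
        "candidate_classes": list(config.candidate_classes),
        "quality_includes_artifacts": config.quality_includes_artifacts,
        "classes": cls,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
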