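"""Batch orchestration: apply one parameter set to every field of an
experiment, in the fixed step order, with a manifest recording every
resolved parameter.

The whole experiment runs with a single parameter block — the schema has no
per-image overrides — so quantitative differences between conditions are
preserved rather than adapted away. Auto-resolved parameters (batch-global
8-bit conversion range, pooled Otsu levels) are resolved once per batch per
channel role, never per image.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .errors import ConfigurationError, InputError, MacroquantError
from .particles import (FieldResult, SizeFilter, analyze_particles,
                        count_nuclei, normalize_per_cell, summarize_condition)
from .preprocess import (default_rolling_ball_radius, max_project,
                         rolling_ball_subtract, to_8bit, ProjectedImage)
from .segmentation import (BinaryMask, apply_mask, make_cell_mask,
                           resolve_threshold_pooled, segment_nuclei,
                           watershed_split)

logger = logging.getLogger("macroquant")


def _strict(cls, d: Mapping, where: str):
    known = set(cls.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where} config "
            f"(per-image overrides are not part of the schema)")
    return d


@dataclass
class PreprocessConfig:
    conversion_mode: str = "batch_global"  # | source_depth | fixed_range
    conversion_min: Optional[float] = None
    conversion_max: Optional[float] = None
    rolling_ball_radius_px: object = "auto"  # int, "auto", or None
    gfp_rolling_ball_radius_px: object = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessConfig":
        return cls(**_strict(cls, d, "preprocess"))


@dataclass
class WatershedConfig:
    enabled: bool = True
    min_peak_separation_px: object = "auto"

    @classmethod
    def from_dict(cls, d: Mapping) -> "WatershedConfig":
        return cls(**_strict(cls, d, "segmentation.watershed"))


@dataclass
class SegmentationConfig:
    dextran_threshold: dict = field(default_factory=lambda: {"method": "li"})
    gfp_threshold: dict = field(default_factory=lambda: {"method": "li"})
    dapi_threshold: dict = field(default_factory=lambda: {"method": "li"})
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    mask_mode: str = "pixel_and"
    overlap_fraction: float = 0.5
    min_cell_area_um2: float = 50.0

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentationConfig":
        d = dict(_strict(cls, d, "segmentation"))
        if "watershed" in d:
            d["watershed"] = WatershedConfig.from_dict(d["watershed"])
        return cls(**d)


@dataclass
class ParticlesConfig:
    size_filter: SizeFilter = field(default_factory=SizeFilter)
    min_nucleus_area_um2: float = 30.0
    exclude_border_particles: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParticlesConfig":
        d = dict(_strict(cls, d, "particles"))
        if "size_filter" in d:
            sf = d["size_filter"]
            _strict(SizeFilter, sf, "particles.size_filter")
            d["size_filter"] = SizeFilter(**sf)
        return cls(**d)


@dataclass
class SampleEntry:
    path: str
    image_id: str
    condition: str
    replicate: str


SAMPLE_COLUMNS = {"path", "image_id", "condition", "replicate"}


@dataclass
class ExperimentConfig:
    """One parameter set for one experiment plus its sample sheet."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    particles: ParticlesConfig = field(default_factory=ParticlesConfig)
    use_gfp_mask: bool = False
    continue_on_error: bool = False
    calibration: Optional[dict] = None  # read_stack override, batch-wide
    random_seed: Optional[int] = None
    output_dir: Optional[str] = None
    samples: Sequence[SampleEntry] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(_strict(cls, d, "experiment"))
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig.from_dict(d["preprocess"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig.from_dict(d["segmentation"])
        if "particles" in d:
            d["particles"] = ParticlesConfig.from_dict(d["particles"])
        if "samples" in d:
            d["samples"] = [SampleEntry(**s) if isinstance(s, Mapping) else s
                            for s in d["samples"]]
        return cls(**d)

    @classmethod
    def from_files(cls, config_path, samples_path=None,
                   output_dir=None) -> "ExperimentConfig":
        with open(config_path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(raw)
        if samples_path is not None:
            cfg.samples = load_sample_sheet(samples_path)
        if output_dir is not None:
            cfg.output_dir = str(output_dir)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for s in self.samples:
            if not Path(s.path).exists():
                raise InputError(f"sample sheet references missing file {s.path}")
        ids = [s.image_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate image_id in sample sheet")

    def to_param_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("samples", None)
        return d


def load_sample_sheet(path) -> list[SampleEntry]:
    """Sample sheet CSV: path, image_id (optional), condition, replicate."""
    df = pd.read_csv(path, dtype=str)
    extra = set(df.columns) - SAMPLE_COLUMNS
    if extra:
        raise ConfigurationError(
            f"sample sheet has unsupported column(s) {sorted(extra)}; "
            "per-image parameter overrides are not part of the schema")
    missing = {"path", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"sample sheet missing column(s) {sorted(missing)}")
    entries = []
    base = Path(path).parent
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        image_id = row.get("image_id") or Path(row["path"]).stem
        entries.append(SampleEntry(path=str(p), image_id=str(image_id),
                                   condition=str(row["condition"]),
                                   replicate=str(row["replicate"])))
    return entries


def _needed_roles(config: ExperimentConfig) -> list[str]:
    roles = ["dextran", "dapi"]
    if config.use_gfp_mask:
        roles.insert(1, "gfp")
    return roles


def _resolve_radius(spec, pixel_size: float) -> Optional[int]:
    if spec is None:
        return None
    if spec == "auto":
        return default_rolling_ball_radius(pixel_size)
    return int(spec)


def _project_roles(stack: mio.CalibratedStack, roles: Sequence[str]) -> dict:
    out = {}
    for role in roles:
        out[role] = max_project(mio.split_channel(stack, role))
    return out


def _resolve_conversion(config: PreprocessConfig, projections: dict) -> dict:
    """Per-role (vmin, vmax) of the batch-wide linear 8-bit map."""
    ranges: dict[str, tuple[float, float]] = {}
    for role, imgs in projections.items():
        if config.conversion_mode == "batch_global":
            vmin = float(min(im.pixels.min() for im in imgs))
            vmax = float(max(im.pixels.max() for im in imgs))
            if vmax <= vmin:
                vmax = vmin + 1.0
        elif config.conversion_mode == "source_depth":
            depth = imgs[0].bit_depth
            vmin, vmax = 0.0, float(2 ** depth - 1)
        elif config.conversion_mode == "fixed_range":
            if config.conversion_min is None or config.conversion_max is None:
                raise ConfigurationError(
                    "fixed_range conversion requires conversion_min and "
                    "conversion_max")
            vmin, vmax = float(config.conversion_min), float(config.conversion_max)
        else:
            raise ConfigurationError(
                f"unknown conversion_mode {config.conversion_mode!r}")
        ranges[role] = (vmin, vmax)
    return ranges


def _correct_channel(projection, config: ExperimentConfig,
                     conv_range: tuple[float, float]) -> ProjectedImage:
    vmin, vmax = conv_range
    img8 = to_8bit(projection.pixels, mode="fixed_range", vmin=vmin, vmax=vmax)
    radius_spec = (config.preprocess.gfp_rolling_ball_radius_px
                   if projection.role == "gfp"
                   else config.preprocess.rolling_ball_radius_px)
    radius = _resolve_radius(radius_spec, projection.pixel_size)
    if radius is not None:
        img8, _ = rolling_ball_subtract(img8, radius)
    return ProjectedImage(
        pixels=img8, pixel_size=projection.pixel_size, role=projection.role,
        provenance={"conversion_min": vmin, "conversion_max": vmax,
                    "rolling_ball_radius_px": radius})


def _quantify_field(corrected: dict, config: ExperimentConfig, image_id: str,
                    condition: str, replicate: str,
                    thresholds: dict) -> FieldResult:
    seg = config.segmentation
    px = corrected["dextran"].pixel_size
    mask = BinaryMask(
        pixels=corrected["dextran"].pixels >= thresholds["dextran"],
        pixel_size=px, source_role="dextran",
        threshold_used=thresholds["dextran"])
    if seg.watershed.enabled:
        sep = seg.watershed.min_peak_separation_px
        sep = int(np.ceil(0.5 / px)) if sep == "auto" else int(sep)
        mask = watershed_split(mask, min_peak_separation_px=sep)
    masked = config.use_gfp_mask
    if masked:
        cells = make_cell_mask(
            corrected["gfp"], {"method": "fixed", "value": thresholds["gfp"]},
            min_cell_area_um2=seg.min_cell_area_um2)
        mask = apply_mask(mask, cells, mode=seg.mask_mode,
                          overlap_fraction=seg.overlap_fraction)
    particles = analyze_particles(
        mask, corrected["dextran"], size_filter=config.particles.size_filter,
        exclude_border_particles=config.particles.exclude_border_particles)
    if masked:
        for p in particles:
            p.in_gfp_mask = True
    nuclei = segment_nuclei(
        corrected["dapi"], {"method": "fixed", "value": thresholds["dapi"]})
    n_nuclei = count_nuclei(
        nuclei, min_nucleus_area_um2=config.particles.min_nucleus_area_um2)
    if n_nuclei == 0:
        logger.warning("%s: zero nuclei detected; field flagged invalid",
                       image_id)
    return normalize_per_cell(particles, n_nuclei, image_id=image_id,
                              condition=condition, replicate=replicate)


def run_field(stack: mio.CalibratedStack, config: ExperimentConfig,
              image_id: str = "field", condition: str = "",
              replicate: str = "") -> FieldResult:
    """Run the full per-field chain on a single stack.

    Auto parameters (conversion range, Otsu levels) are resolved from this
    field alone; within a batch use :func:`run_batch`, which resolves them
    once from the pooled batch.
    """
    roles = _needed_roles(config)
    projections = _project_roles(stack, roles)
    conv = _resolve_conversion(config.preprocess,
                               {r: [projections[r]] for r in roles})
    corrected = {r: _correct_channel(projections[r], config, conv[r])
                 for r in roles}
    thresholds = _resolve_batch_thresholds({k: [v] for k, v in corrected.items()},
                                           config)
    return _quantify_field(corrected, config, image_id, condition, replicate,
                           thresholds)


def _resolve_batch_thresholds(corrected_by_role: dict,
                              config: ExperimentConfig) -> dict:
    spec_of = {"dextran": config.segmentation.dextran_threshold,
               "gfp": config.segmentation.gfp_threshold,
               "dapi": config.segmentation.dapi_threshold}
    out = {}
    for role, imgs in corrected_by_role.items():
        try:
            out[role] = resolve_threshold_pooled(
                [im.pixels for im in imgs], spec_of[role])
        except InputError:
            # constant batch (e.g. an entirely empty channel): no automatic
            # level exists, and nothing should be segmented
            const = int(imgs[0].pixels.flat[0])
            out[role] = min(255, const + 1)
            logger.warning("channel %s is constant across the batch; "
                           "threshold set above it (%d)", role, out[role])
    return out


def run_batch(config: ExperimentConfig) -> dict:
    """Process every sample-sheet image with the single batch parameter set.

    Returns ``{"results", "summaries", "manifest", "paths", "failures"}``;
    unreadable images abort the batch unless ``continue_on_error`` is set.
    """
    if not config.samples:
        raise ConfigurationError("experiment has no samples")
    roles = _needed_roles(config)
    failures: list[dict] = []

    projections: dict[str, dict] = {}
    order: list[SampleEntry] = []
    for entry in sorted(config.samples, key=lambda s: s.image_id):
        t0 = time.perf_counter()
        try:
            stack = mio.read_stack(entry.path,
                                   calibration_override=config.calibration)
            projections[entry.image_id] = _project_roles(stack, roles)
            order.append(entry)
        except MacroquantError as exc:
            if not config.continue_on_error:
                raise type(exc)(f"{entry.image_id}: {exc}") from exc
            logger.error("%s: failed to read (%s)", entry.image_id, exc)
            failures.append({"image_id": entry.image_id, "error": str(exc)})
        logger.info("read+project %s (%.2fs)", entry.image_id,
                    time.perf_counter() - t0)
    if not order:
        raise InputError("no readable fields in batch")

    by_role = {r: [projections[e.image_id][r] for e in order] for r in roles}
    conv = _resolve_conversion(config.preprocess, by_role)

    corrected: dict[str, dict] = {}
    for entry in order:
        t0 = time.perf_counter()
        corrected[entry.image_id] = {
            r: _correct_channel(projections[entry.image_id][r], config, conv[r])
            for r in roles}
        logger.info("corrected %s (%.2fs)", entry.image_id,
                    time.perf_counter() - t0)
    thresholds = _resolve_batch_thresholds(
        {r: [corrected[e.image_id][r] for e in order] for r in roles}, config)

    results: list[FieldResult] = []
    for entry in order:
        t0 = time.perf_counter()
        try:
            res = _quantify_field(corrected[entry.image_id], config,
                                  entry.image_id, entry.condition,
                                  entry.replicate, thresholds)
            results.append(res)
        except MacroquantError as exc:
            if not config.continue_on_error:
                raise type(exc)(f"{entry.image_id}: {exc}") from exc
            logger.error("%s: failed to quantify (%s)", entry.image_id, exc)
            failures.append({"image_id": entry.image_id, "error": str(exc)})
        logger.info("quantified %s (%.2fs)", entry.image_id,
                    time.perf_counter() - t0)

    summaries = []
    by_condition: dict[str, dict[str, list[FieldResult]]] = {}
    for res in results:
        by_condition.setdefault(res.condition, {}).setdefault(
            res.replicate, []).append(res)
    for cond in sorted(by_condition):
        s = summarize_condition(cond, by_condition[cond])
        if s.under_sampled:
            logger.warning("condition %s: a replicate has fewer than 200 "
                           "cells", cond)
        summaries.append(s)

    manifest_params = {
        "config": config.to_param_dict(),
        "resolved": {
            "conversion_ranges": {r: list(conv[r]) for r in roles},
            "thresholds": thresholds,
            "rolling_ball_radius_px": {
                r: corrected[order[0].image_id][r].provenance[
                    "rolling_ball_radius_px"] for r in roles},
        },
        "failures": failures,
    }
    paths = None
    if config.output_dir is not None:
        paths = mio.write_results(results, summaries, config.output_dir,
                                  params=manifest_params)
    return {"results": results, "summaries": summaries,
            "manifest": manifest_params, "paths": paths, "failures": failures}
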