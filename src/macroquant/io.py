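"""Reading calibrated multi-channel z-stacks and writing tabular results.

No image math lives here: this module only resolves axes, physical
calibration (um/px, um z-spacing) and channel roles, and serializes results.

Axis convention throughout the package: ``(z, channel, y, x)``, y increasing
downward, x rightward, 0-based coordinates, half-open bounding boxes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, InputError

ROLES = ("dextran", "gfp", "dapi")

#: default mapping for RGB-interleaved files: red -> dextran, green -> gfp,
#: blue -> dapi, mirroring the conventional dextran-TMR / GFP / DAPI usage.
RGB_ROLE_MAP = {"dextran": 0, "gfp": 1, "dapi": 2}

PER_FIELD_COLUMNS = [
    "image_id", "condition", "replicate", "mp_count", "mp_total_area_um2",
    "mp_avg_size_um2", "mp_intden", "nucleus_count", "mp_per_cell",
    "mp_per_100_cells",
]
PER_PARTICLE_COLUMNS = [
    "image_id", "particle_id", "area_um2", "equiv_diameter_um",
    "centroid_x_px", "centroid_y_px", "integrated_density", "in_gfp_mask",
]
SUMMARY_COLUMNS = [
    "condition", "mean_mp_per_100_cells", "sem", "n_replicates",
    "n_cells_total",
]


@dataclass
class CalibratedStack:
    """Multi-channel z-stack with physical calibration.

    Parameters
    ----------
    voxels
        Intensity array with axes ``(z, channel, y, x)``.
    pixel_size
        Isotropic x/y pixel size in um.
    z_spacing
        Spacing between slices in um; may be ``None`` for single-slice stacks.
    channel_roles
        Mapping from role (``dextran``/``gfp``/``dapi``) to channel index.
    """

    voxels: np.ndarray
    pixel_size: float
    z_spacing: float | None
    channel_roles: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:  # (z, y, x) -> insert channel axis
            self.voxels = self.voxels[:, None, :, :]
        if self.voxels.ndim != 4:
            raise InputError(
                f"stack must be 3-D or 4-D, got ndim={self.voxels.ndim}")
        if not self.pixel_size or self.pixel_size <= 0:
            raise ConfigurationError(
                f"pixel_size must be > 0, got {self.pixel_size!r}")
        if self.n_slices > 1 and (self.z_spacing is None or self.z_spacing <= 0):
            raise ConfigurationError(
                "z_spacing must be > 0 for stacks with more than one slice")
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown channel role {role!r}")
            if not 0 <= idx < self.n_channels:
                raise ConfigurationError(
                    f"channel role {role!r} declared at index {idx} but stack "
                    f"has {self.n_channels} channel(s)")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    @property
    def bit_depth(self) -> int:
        return self.voxels.dtype.itemsize * 8


@dataclass
class ChannelImage:
    """One 2-D slice of one channel, carrying calibration and role."""

    pixels: np.ndarray
    pixel_size: float
    role: str
    bit_depth: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError("ChannelImage pixels must be 2-D")


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (z, channel, y, x), inserting singletons."""
    axes = axes.upper().replace("S", "C")  # RGB samples behave as channels
    if "Q" in axes:  # unknown axis tifffile could not identify
        raise InputError(f"cannot interpret TIFF axes {axes!r}")
    for ax in axes:
        if ax not in "TZCYX":
            raise InputError(f"unsupported TIFF axis {ax!r} in {axes!r}")
    if "T" in axes:
        if data.shape[axes.index("T")] != 1:
            raise InputError("time series are not supported")
        data = np.take(data, 0, axis=axes.index("T"))
        axes = axes.replace("T", "")
    for ax in "ZC":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "ZCYX"]
    return np.transpose(data, order)


def _ome_calibration(ome_xml: str) -> dict:
    """Pull PhysicalSizeX/Z and channel names out of an OME-XML blob."""
    out: dict = {}
    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome_xml)
    if m:
        out["pixel_size"] = float(m.group(1))
    m = re.search(r'PhysicalSizeZ="([0-9.eE+-]+)"', ome_xml)
    if m:
        out["z_spacing"] = float(m.group(1))
    names = re.findall(r'<Channel[^>]*\bName="([^"]+)"', ome_xml)
    if names:
        roles = {}
        for i, name in enumerate(names):
            key = name.strip().lower()
            if key in ROLES:
                roles[key] = i
        if roles:
            out["channel_roles"] = roles
    return out


def _resolution_tag_pixel_size(page) -> float | None:
    """Physical pixel size in um from classic TIFF resolution tags."""
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = xres
    if num == 0:
        return None
    px_per_unit = num / den
    unit = int(unit)
    if unit == 3:  # centimeter
        return 10000.0 / px_per_unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    return None


def read_stack(path, calibration_override: Mapping | None = None) -> CalibratedStack:
    """Read a TIFF / OME-TIFF z-stack and resolve calibration and roles.

    Calibration precedence: explicit override > OME metadata > TIFF
    resolution tags; a stack with no resolvable pixel size is a
    configuration error rather than a silent 1 um/px assumption.
    """
    path = Path(path)
    override = dict(calibration_override or {})
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tif.ome_metadata or ""
            page = tif.pages[0]
            tag_px = _resolution_tag_pixel_size(page)
            is_rgb = "S" in axes.upper()
    except (OSError, ValueError, IndexError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read TIFF stack {path}: {exc}") from exc

    voxels = _normalize_axes(data, axes)
    ome = _ome_calibration(ome_xml) if ome_xml else {}

    pixel_size = override.get("pixel_size", ome.get("pixel_size", tag_px))
    if pixel_size is None:
        raise ConfigurationError(
            f"{path}: no pixel size in metadata and no calibration_override")
    z_spacing = override.get("z_spacing", ome.get("z_spacing"))

    roles = override.get("channel_roles")
    if roles is None:
        roles = ome.get("channel_roles")
    if roles is None:
        n_ch = voxels.shape[1]
        if is_rgb and n_ch >= 3:
            roles = {r: i for r, i in RGB_ROLE_MAP.items() if i < n_ch}
        elif n_ch == 1:
            roles = {"dextran": 0}
        else:
            raise ConfigurationError(
                f"{path}: {n_ch} channels but no channel_roles in metadata "
                "or override")
    return CalibratedStack(voxels=voxels, pixel_size=float(pixel_size),
                           z_spacing=z_spacing, channel_roles=dict(roles))


def write_stack(stack: CalibratedStack, path) -> None:
    """Write a stack as OME-TIFF with calibration and channel-name metadata.

    Integer voxel data round-trips bit-exactly through :func:`read_stack`.
    """
    path = Path(path)
    names = [f"channel{i}" for i in range(stack.n_channels)]
    for role, idx in stack.channel_roles.items():
        names[idx] = role
    metadata = {
        "axes": "ZCYX",
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeY": stack.pixel_size,
        "Channel": {"Name": names},
    }
    if stack.z_spacing is not None:
        metadata["PhysicalSizeZ"] = stack.z_spacing
    tifffile.imwrite(path, stack.voxels, ome=True, metadata=metadata,
                     photometric="minisblack")


def split_channel(stack: CalibratedStack, role: str) -> list[ChannelImage]:
    """Extract one channel as a z-ordered list of 2-D images.

    The returned pixel arrays are copies: processing one channel can never
    mutate another channel's data.
    """
    if role not in stack.channel_roles:
        raise ConfigurationError(
            f"channel role {role!r} not declared (have "
            f"{sorted(stack.channel_roles)})")
    idx = stack.channel_roles[role]
    depth = stack.bit_depth
    return [
        ChannelImage(pixels=stack.voxels[z, idx].copy(),
                     pixel_size=stack.pixel_size, role=role, bit_depth=depth)
        for z in range(stack.n_slices)
    ]


def _field_row(r) -> dict:
    return {
        "image_id": r.image_id, "condition": r.condition,
        "replicate": r.replicate, "mp_count": r.mp_count,
        "mp_total_area_um2": r.mp_total_area_um2,
        "mp_avg_size_um2": r.mp_avg_size_um2, "mp_intden": r.mp_intden_total,
        "nucleus_count": r.nucleus_count,
        "mp_per_cell": r.mp_per_cell if r.valid else "",
        "mp_per_100_cells": r.mp_per_100_cells if r.valid else "",
    }


def write_results(results: Sequence, summaries: Sequence, out_dir,
                  params: Mapping | None = None) -> dict[str, Path]:
    """Write per-field, per-particle and summary CSVs plus a JSON manifest.

    Returns a mapping of logical name to written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} not writable: {exc}") from exc

    field_df = pd.DataFrame(
        [_field_row(r) for r in results], columns=PER_FIELD_COLUMNS)
    particle_rows = []
    for r in results:
        for p in r.particles:
            particle_rows.append({
                "image_id": r.image_id, "particle_id": p.label,
                "area_um2": p.area_um2,
                "equiv_diameter_um": p.equiv_diameter_um,
                "centroid_x_px": p.centroid[1], "centroid_y_px": p.centroid[0],
                "integrated_density": p.integrated_density,
                "in_gfp_mask": "" if p.in_gfp_mask is None else p.in_gfp_mask,
            })
    particle_df = pd.DataFrame(particle_rows, columns=PER_PARTICLE_COLUMNS)
    summary_df = pd.DataFrame(
        [{
            "condition": s.condition,
            "mean_mp_per_100_cells": s.mean_mp_per_100_cells,
            "sem": "" if s.sem is None else s.sem,
            "n_replicates": s.n_replicates,
            "n_cells_total": s.n_cells_total,
        } for s in summaries],
        columns=SUMMARY_COLUMNS)

    paths = {
        "per_field": out_dir / "per_field.csv",
        "per_particle": out_dir / "per_particle.csv",
        "summary": out_dir / "summary.csv",
        "manifest": out_dir / "manifest.json",
    }
    field_df.to_csv(paths["per_field"], index=False)
    particle_df.to_csv(paths["per_particle"], index=False)
    summary_df.to_csv(paths["summary"], index=False)
    manifest = {"parameters": dict(params or {}),
                "n_fields": len(field_df), "n_particles": len(particle_df)}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return paths
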