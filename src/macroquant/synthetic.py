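"""Synthetic fluorescence fields with known ground truth.

Emulates adherent HEK293-like monolayers imaged as 3-channel confocal
z-stacks: elliptical cells at 50-75% confluency each with one nucleus,
macropinosomes (0.5-5 um, log-uniform) concentrated near cell peripheries,
optional sub-resolution endocytic confounders (0.1-0.2 um), a smooth
polynomial illumination gradient, Gaussian optical blur, and Poisson photon
plus Gaussian read noise. Every rendered structure is recorded in the
ground-truth scene so pipeline detections can be scored against it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import GenerationError, InputError
from .io import CalibratedStack

CHANNEL_ORDER = {"dextran": 0, "gfp": 1, "dapi": 2}


@dataclass
class SceneParams:
    """Tunable knobs of the synthetic field generator.

    Lengths in um, amplitudes in detector counts. ``snr`` is the peak
    structure amplitude over the background noise standard deviation
    (sqrt of photon variance at the mean background plus read variance).
    """

    field_size_px: int = 512
    pixel_size_um: float = 0.3
    n_z: int = 11
    z_spacing_um: float = 0.5
    confluency: float = 0.6
    cell_axis_um: tuple[float, float] = (10.0, 20.0)  # full-axis range
    nucleus_axis_um: tuple[float, float] = (4.0, 7.0)
    gfp_fraction: float = 1.0
    mean_mp_per_cell: float = 5.0
    n_mp_total: Optional[int] = None  # exact total, overrides the Poisson draw
    mp_diameter_um: tuple[float, float] = (0.5, 5.0)  # log-uniform
    mp_annulus: tuple[float, float] = (0.70, 0.95)  # radial fraction band
    confounders_per_cell: float = 0.0
    confounder_diameter_um: tuple[float, float] = (0.1, 0.2)
    background_level: float = 100.0
    background_gradient: float = 40.0
    read_noise_sigma: float = 3.0
    snr: float = 10.0
    sigma_xy_um: float = 0.15
    noise: bool = True

    @property
    def field_size_um(self) -> float:
        return self.field_size_px * self.pixel_size_um


@dataclass
class Cell:
    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]
    angle_rad: float
    gfp_positive: bool
    nucleus_center_um: tuple[float, float]
    nucleus_semi_axes_um: tuple[float, float]


@dataclass
class Structure:
    cls: str  # macropinosome | vesicle
    x_um: float
    y_um: float
    z_um: float
    diameter_um: float
    cell_index: int


@dataclass
class SyntheticScene:
    """Ground-truth description of one synthetic field."""

    field_id: str
    params: SceneParams
    seed: int
    cells: list[Cell] = field(default_factory=list)
    structures: list[Structure] = field(default_factory=list)

    @property
    def macropinosomes(self) -> list[Structure]:
        return [s for s in self.structures if s.cls == "macropinosome"]

    def truth_dict(self) -> dict:
        entries = []
        for c in self.cells:
            entries.append({
                "class": "cell", "x_um": c.center_um[0], "y_um": c.center_um[1],
                "z_um": 0.0, "diameter_um": sum(c.semi_axes_um)})
            entries.append({
                "class": "nucleus", "x_um": c.nucleus_center_um[0],
                "y_um": c.nucleus_center_um[1], "z_um": 0.0,
                "diameter_um": sum(c.nucleus_semi_axes_um)})
        for s in self.structures:
            entries.append({
                "class": s.cls, "x_um": s.x_um, "y_um": s.y_um,
                "z_um": s.z_um, "diameter_um": s.diameter_um})
        return {"field_id": self.field_id,
                "pixel_size_um": self.params.pixel_size_um,
                "structures": entries}

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)


def _ellipse_mask(shape: tuple[int, int], center_px: tuple[float, float],
                  semi_px: tuple[float, float], angle: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse; center is (x, y) in px."""
    h, w = shape
    cx, cy = center_px
    a, b = semi_px
    r = int(math.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    out = np.zeros(shape, dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    out[y0:y1, x0:x1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _boundary_radius(semi_axes: tuple[float, float], phi: float) -> float:
    """Distance from center to the ellipse boundary along body-frame angle phi."""
    a, b = semi_axes
    return a * b / math.hypot(b * math.cos(phi), a * math.sin(phi))


def _place_cells(params: SceneParams, rng: np.random.Generator) -> list[Cell]:
    """Non-overlapping elliptical cells at the requested confluency.

    Cells are seeded at the minimum allowed size on a jittered hexagonal
    grid sized for the target coverage, then grown axis-by-axis in small
    increments — each cell expanding until it reaches its sampled target
    axes or jams against a neighbour — the way an adherent monolayer
    spreads to confluency. Growth stops globally the moment the target
    coverage is reached. Cell footprints stay pairwise disjoint (they may
    touch), may overhang the field edge as in real fields of view, and
    every nucleus lies fully inside the field.
    """
    n_px = params.field_size_px
    px = params.pixel_size_um
    field_um = params.field_size_um
    lo, hi = params.cell_axis_um
    target = params.confluency
    if target <= 0:
        return []
    shape = (n_px, n_px)
    total_px = n_px * n_px
    overhang = lo / 2
    mean_area = math.pi * ((lo + hi) / 4.0) ** 2
    density = min(1.15, 1.5 * target)
    spacing = max(lo + 1.0, math.sqrt(mean_area / (density * math.sqrt(3) / 2)))
    occ = np.zeros(shape, dtype=np.uint8)

    row_h = spacing * math.sqrt(3) / 2
    n_rows = int((field_um + 2 * overhang) / row_h) + 1
    n_cols = int((field_um + 2 * overhang) / spacing) + 1
    sites = [(-overhang + (j + (0.5 if i % 2 else 0.0)) * spacing
              + rng.uniform(-0.07, 0.07) * spacing,
              -overhang + (i + 0.5) * row_h
              + rng.uniform(-0.07, 0.07) * spacing)
             for i in range(n_rows) for j in range(n_cols)]

    seeds: list[dict] = []
    covered = 0
    for cx, cy in sites:
        angle = rng.uniform(0, math.pi)
        cap_a = rng.uniform(lo, hi) / 2
        cap_b = rng.uniform(lo, hi) / 2
        a = b = lo / 2
        cand = _ellipse_mask(shape, (cx / px, cy / px), (a / px, b / px), angle)
        if not cand.any():
            continue
        if occ[cand].any():
            continue
        occ[cand] += 1
        covered += int(cand.sum())
        seeds.append(dict(cx=cx, cy=cy, angle=angle, cap_a=cap_a, cap_b=cap_b,
                          a=a, b=b, mask=cand, grow_a=True, grow_b=True))

    alive = list(range(len(seeds)))
    rounds = 0
    step = 1.05
    while alive and covered / total_px < target and rounds < 100:
        rounds += 1
        rng.shuffle(alive)
        still = []
        for i in alive:
            c = seeds[i]
            grew = False
            for axis in ("a", "b"):
                if not c["grow_" + axis]:
                    continue
                cap = c["cap_" + axis]
                new = min(cap, c[axis] * step)
                if new <= c[axis] + 1e-9:
                    c["grow_" + axis] = False
                    continue
                a = new if axis == "a" else c["a"]
                b = c["b"] if axis == "a" else new
                cand = _ellipse_mask(shape, (c["cx"] / px, c["cy"] / px),
                                     (a / px, b / px), c["angle"])
                occ[c["mask"]] -= 1
                if occ[cand].any():
                    occ[c["mask"]] += 1
                    c["grow_" + axis] = False
                    continue
                occ[cand] += 1
                covered += int(cand.sum()) - int(c["mask"].sum())
                c["mask"] = cand
                c[axis] = new
                grew = True
                if covered / total_px >= target:
                    break
            if covered / total_px >= target:
                if grew:
                    still.append(i)
                break
            if grew:
                still.append(i)
        alive = still

    coverage = covered / total_px
    if coverage < target - 0.05:
        raise GenerationError(
            f"could only reach {coverage:.2f} cell coverage for requested "
            f"confluency {target:.2f}; lower the density or cell size range")

    nlo, nhi = params.nucleus_axis_um
    margin = nhi / 2 + 1.0  # nucleus must fit fully inside the field
    nuc_occ = np.zeros(shape, dtype=bool)
    sep = np.ones((5, 5), dtype=bool)  # >= 2 px between neighbouring nuclei
    cells: list[Cell] = []
    for c in seeds:
        na = rng.uniform(nlo, nhi) / 2
        nb = rng.uniform(nlo, nhi) / 2
        slack = max(0.0, min(c["a"], c["b"]) - max(na, nb))
        ncx = ncy = None
        for _ in range(8):  # clamped border nuclei must not collide
            off = rng.uniform(-0.3, 0.3, size=2) * slack
            tx = min(max(c["cx"] + off[0], margin), field_um - margin)
            ty = min(max(c["cy"] + off[1], margin), field_um - margin)
            nmask = _ellipse_mask(shape, (tx / px, ty / px),
                                  (na / px, nb / px), c["angle"])
            if not (ndi.binary_dilation(nmask, structure=sep) & nuc_occ).any():
                ncx, ncy = tx, ty
                nuc_occ |= nmask
                break
        if ncx is None:
            continue  # no collision-free spot for this border cell's nucleus
        cells.append(Cell(
            center_um=(c["cx"], c["cy"]), semi_axes_um=(c["a"], c["b"]),
            angle_rad=c["angle"],
            gfp_positive=bool(rng.random() < params.gfp_fraction),
            nucleus_center_um=(ncx, ncy), nucleus_semi_axes_um=(na, nb)))
    return cells


def generate_scene(params: SceneParams, seed: int,
                   field_id: str = "field") -> SyntheticScene:
    """Deterministically generate one ground-truth scene."""
    rng = np.random.default_rng(seed)
    cells = _place_cells(params, rng)
    structures: list[Structure] = []
    field_um = params.field_size_um
    z_lo = params.z_spacing_um
    z_hi = max(z_lo, (params.n_z - 2) * params.z_spacing_um)
    d_lo, d_hi = params.mp_diameter_um
    u_lo, u_hi = params.mp_annulus

    placed: list[tuple[float, float, float]] = []  # (x, y, radius) of all structures
    clearance = 1.2  # um kept between structure edges so blur cannot fuse them

    def place_in_cell(cell: Cell, diameter: float, annulus: bool
                      ) -> Optional[tuple[float, float]]:
        """Sample a structure center in the cell, inside the field, clear of
        previously placed structures. Discrete organelles do not overlap: a
        cell whose interior is packed full simply accommodates no further
        structure, and ``None`` is returned.
        """
        ca, sa = math.cos(cell.angle_rad), math.sin(cell.angle_rad)
        half = diameter / 2
        for attempt in range(60):
            phi = rng.uniform(0, 2 * math.pi)
            rb = _boundary_radius(cell.semi_axes_um, phi)
            if annulus and attempt < 40:
                u = rng.uniform(u_lo, u_hi)
            else:  # relax toward the whole cell if the annulus is crowded
                u = math.sqrt(rng.random()) * 0.95
            u = min(u, max(0.0, 1.0 - half / rb))  # keep disk inside the cell
            bx, by = u * rb * math.cos(phi), u * rb * math.sin(phi)
            x = cell.center_um[0] + bx * ca - by * sa
            y = cell.center_um[1] + bx * sa + by * ca
            if not (half <= x <= field_um - half
                    and half <= y <= field_um - half):
                continue
            margin = min((math.hypot(x - ox, y - oy) - half - orad
                          for ox, oy, orad in placed), default=math.inf)
            if margin >= clearance:
                placed.append((x, y, half))
                return x, y
        return None

    # uptake scales with cell size: expected load proportional to footprint
    # area, normalized so the across-cell mean equals mean_mp_per_cell
    cell_areas = np.array([c.semi_axes_um[0] * c.semi_axes_um[1]
                           for c in cells], dtype=float)
    weights = cell_areas / cell_areas.sum()
    if params.n_mp_total is not None:
        mp_counts = rng.multinomial(params.n_mp_total, weights)
    else:
        mp_counts = rng.poisson(
            params.mean_mp_per_cell * weights * len(cells))
    deferred = 0
    for ci, cell in enumerate(cells):
        for _ in range(int(mp_counts[ci])):
            d = math.exp(rng.uniform(math.log(d_lo), math.log(d_hi)))
            pos = place_in_cell(cell, d, annulus=True)
            if pos is None:
                deferred += 1
                continue
            structures.append(Structure(
                cls="macropinosome", x_um=pos[0], y_um=pos[1],
                z_um=rng.uniform(z_lo, z_hi), diameter_um=d, cell_index=ci))
        n_ves = rng.poisson(params.confounders_per_cell)
        v_lo, v_hi = params.confounder_diameter_um
        for _ in range(n_ves):
            d = rng.uniform(v_lo, v_hi)
            pos = place_in_cell(cell, d, annulus=False)
            if pos is None:
                continue
            structures.append(Structure(
                cls="vesicle", x_um=pos[0], y_um=pos[1],
                z_um=rng.uniform(z_lo, z_hi), diameter_um=d, cell_index=ci))
    # re-home crowded-out draws into cells that still have room, so the
    # realized total tracks the sampled total (and the exact requested
    # total when n_mp_total is set)
    attempts = 0
    while deferred and attempts < 20 * max(len(cells), 1):
        attempts += 1
        ci = int(rng.integers(len(cells)))
        d = math.exp(rng.uniform(math.log(d_lo), math.log(d_hi)))
        pos = place_in_cell(cells[ci], d, annulus=True)
        if pos is not None:
            structures.append(Structure(
                cls="macropinosome", x_um=pos[0], y_um=pos[1],
                z_um=rng.uniform(z_lo, z_hi), diameter_um=d,
                cell_index=ci))
            deferred -= 1
    if deferred and params.n_mp_total is not None:
        raise GenerationError(
            f"could not place {deferred} of the requested "
            f"{params.n_mp_total} macropinosomes; lower the density")
    return SyntheticScene(field_id=field_id, params=params, seed=int(seed),
                          cells=cells, structures=structures)


def _draw_disk(canvas: np.ndarray, x_px: float, y_px: float,
               radius_px: float, amplitude: float) -> None:
    """Max-composite an anti-aliased disk onto a float canvas."""
    h, w = canvas.shape
    r = int(math.ceil(radius_px)) + 2
    y0, y1 = max(0, int(y_px) - r), min(h, int(y_px) + r + 1)
    x0, x1 = max(0, int(x_px) - r), min(w, int(x_px) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - x_px, yy - y_px)
    cov = np.clip(radius_px - dist + 0.5, 0.0, 1.0)
    # sub-pixel disks never exceed their area coverage of the center pixel
    if radius_px < 0.5:
        cov *= math.pi * radius_px ** 2
    region = canvas[y0:y1, x0:x1]
    np.maximum(region, cov * amplitude, out=region)


def _background(params: SceneParams, rng: np.random.Generator,
                shape: tuple[int, int]) -> np.ndarray:
    """Smooth low-order polynomial illumination surface in [level, level+grad]."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    xh, yh = xs / max(w - 1, 1), ys / max(h - 1, 1)
    coef = rng.uniform(-1.0, 1.0, size=5)
    surf = (coef[0] * xh + coef[1] * yh + coef[2] * xh * yh
            + coef[3] * xh ** 2 + coef[4] * yh ** 2)
    lo, hi = surf.min(), surf.max()
    if hi - lo < 1e-12:
        surf = np.zeros_like(surf)
    else:
        surf = (surf - lo) / (hi - lo)
    return params.background_level + params.background_gradient * surf


def render_stack(scene: SyntheticScene) -> CalibratedStack:
    """Render a scene into a calibrated 3-channel uint16 z-stack.

    A structure is drawn as a disk in every slice its z-extent overlaps (at
    least the nearest slice) — with the spherical cross-section radius of
    that slice, so the maximum-intensity projection shows the equatorial
    diameter and the z-profile peaks at the structure's z-center — and
    blurred with a Gaussian approximating the optical PSF. A disk of
    radius r blurred by sigma keeps a fraction
    ``1 - exp(-r^2 / 2 sigma^2)`` of its peak; disks are pre-compensated
    for that attenuation so every resolvable structure's rendered peak over
    the local background equals ``snr * sqrt(background_level +
    read_noise_sigma**2)``. The compensation is capped at the smallest
    resolvable radius (0.25 um, half the minimum macropinosome diameter):
    sub-resolution vesicles keep their physical PSF attenuation relative to
    that limit and therefore render dimmer, as they do under a real
    objective where peak brightness falls with dye volume.
    """
    p = scene.params
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0xC0FFEE]))
    n, px = p.field_size_px, p.pixel_size_um
    shape = (n, n)
    sigma_px = p.sigma_xy_um / px
    noise_sd = math.sqrt(p.background_level + p.read_noise_sigma ** 2)
    amp = p.snr * noise_sd
    dex_bg = _background(p, rng, shape)
    stack = np.zeros((p.n_z, 3, n, n), dtype=np.float64)

    def psf_kept(r_px: float) -> float:
        return 1.0 - math.exp(-r_px ** 2 / (2 * sigma_px ** 2))

    r_res_px = 0.25 / px  # smallest resolvable radius in px
    z_of = np.arange(p.n_z) * p.z_spacing_um
    half_section = p.z_spacing_um / 2  # each slice integrates this much z
    dex_slices = [np.zeros(shape) for _ in range(p.n_z)]

    def chord_integral(h: float, u0: float, u1: float) -> float:
        """Integral of the sphere chord 2*sqrt(h^2-u^2) over [u0, u1]."""
        u0 = min(max(u0, -h), h)
        u1 = min(max(u1, -h), h)
        if u1 <= u0:
            return 0.0

        def prim(u: float) -> float:
            return u * math.sqrt(max(h * h - u * u, 0.0)) + \
                h * h * math.asin(max(-1.0, min(1.0, u / h)))
        return prim(u1) - prim(u0)

    for s in scene.structures:
        half = s.diameter_um / 2
        # dye captured by each optical section: the column through the
        # sphere integrated over the section; the z-profile therefore peaks
        # at the slice closest to the structure's z-center, and structures
        # thinner than one section land entirely in the nearest slice
        captured = np.array([
            chord_integral(half, z_of[z] - s.z_um - half_section,
                           z_of[z] - s.z_um + half_section)
            for z in range(p.n_z)])
        if captured.max() <= 0:
            continue
        captured /= captured.max()  # peak slice reaches nominal SNR
        if sigma_px > 0:
            # compensate the PSF attenuation of the equatorial disk
            boost = 1.0 / psf_kept(max(half / px, r_res_px))
        else:
            boost = 1.0
        for z in range(p.n_z):
            if captured[z] <= 0:
                continue
            dz_eff = max(0.0, abs(z_of[z] - s.z_um) - half_section)
            r_um = math.sqrt(max(half ** 2 - dz_eff ** 2, 0.0))
            _draw_disk(dex_slices[z], s.x_um / px, s.y_um / px, r_um / px,
                       amp * boost * captured[z])
    for z in range(p.n_z):
        dex = dex_slices[z]
        if sigma_px > 0:
            dex = ndi.gaussian_filter(dex, sigma_px)
        stack[z, 0] = dex + dex_bg

    gfp = np.zeros(shape)
    dapi = np.zeros(shape)
    for c in scene.cells:
        if c.gfp_positive:
            foot = _ellipse_mask(shape, (c.center_um[0] / px, c.center_um[1] / px),
                                 (c.semi_axes_um[0] / px, c.semi_axes_um[1] / px),
                                 c.angle_rad)
            gfp[foot] = np.maximum(gfp[foot], amp)
        nuc = _ellipse_mask(
            shape, (c.nucleus_center_um[0] / px, c.nucleus_center_um[1] / px),
            (c.nucleus_semi_axes_um[0] / px, c.nucleus_semi_axes_um[1] / px),
            c.angle_rad)
        dapi[nuc] = np.maximum(dapi[nuc], amp)
        gfp[nuc] *= 0.25  # nuclei appear as dark holes in the GFP channel
    if sigma_px > 0:
        gfp = ndi.gaussian_filter(gfp, sigma_px)
        dapi = ndi.gaussian_filter(dapi, sigma_px)
    low_bg = 0.2 * p.background_level
    for z in range(p.n_z):
        stack[z, 1] = gfp + low_bg
        stack[z, 2] = dapi + low_bg

    if p.noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
        stack += rng.normal(0.0, p.read_noise_sigma, size=stack.shape)
    voxels = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    return CalibratedStack(voxels=voxels, pixel_size=px,
                           z_spacing=p.z_spacing_um,
                           channel_roles=dict(CHANNEL_ORDER))


@dataclass
class DetectionScore:
    """Detection-vs-truth tally for macropinosome centers."""

    n_truth: int
    n_detected: int
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    count_error_fraction: float


def _score_from_counts(n_truth: int, n_detected: int, tp: int) -> DetectionScore:
    fp = n_detected - tp
    fn = n_truth - tp
    precision = tp / n_detected if n_detected else 1.0
    recall = tp / n_truth if n_truth else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    cef = abs(n_detected - n_truth) / n_truth if n_truth else 0.0
    return DetectionScore(n_truth=n_truth, n_detected=n_detected,
                          true_positives=tp, false_positives=fp,
                          false_negatives=fn, precision=precision,
                          recall=recall, f1=f1, count_error_fraction=cef)


def score_detections(truth, detections, match_radius_um: float = 1.0,
                     pixel_size_um: float | None = None) -> DetectionScore:
    """Greedy nearest-first one-to-one matching of detections to truth.

    ``truth`` is a ground-truth dict (or path to the JSON) whose
    macropinosome entries are matched; ``detections`` is a sequence of
    ``(x_um, y_um)`` centers, a sequence of Particle objects (centroids in
    px, converted with ``pixel_size_um`` or the truth's pixel size), or a
    per-particle DataFrame with ``centroid_x_px``/``centroid_y_px`` columns.
    """
    if match_radius_um <= 0:
        raise InputError("match_radius_um must be > 0")
    if isinstance(truth, (str, Path)):
        with open(truth) as fh:
            truth = json.load(fh)
    px = pixel_size_um or truth.get("pixel_size_um")
    truth_xy = np.array([[s["x_um"], s["y_um"]]
                         for s in truth["structures"]
                         if s["class"] == "macropinosome"], dtype=float)
    truth_xy = truth_xy.reshape(-1, 2)

    det_xy: np.ndarray
    if hasattr(detections, "columns"):  # per-particle DataFrame
        if "image_id" in detections.columns and len(detections):
            ids = set(detections["image_id"].unique())
            if truth.get("field_id") is not None and ids - {truth["field_id"]}:
                raise InputError(
                    f"detections cover fields {sorted(ids)} but truth is for "
                    f"{truth['field_id']!r}")
        det_xy = detections[["centroid_x_px", "centroid_y_px"]].to_numpy(float)
        det_xy = det_xy * float(px)
    else:
        rows = []
        for d in detections:
            if hasattr(d, "centroid"):
                rows.append((d.centroid[1] * float(px), d.centroid[0] * float(px)))
            else:
                rows.append((float(d[0]), float(d[1])))
        det_xy = np.array(rows, dtype=float).reshape(-1, 2)

    n_t, n_d = len(truth_xy), len(det_xy)
    tp = 0
    if n_t and n_d:
        diff = truth_xy[:, None, :] - det_xy[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        pairs = [(dist[i, j], i, j) for i in range(n_t) for j in range(n_d)
                 if dist[i, j] <= match_radius_um]
        pairs.sort(key=lambda t: (t[0], t[1], t[2]))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, i, j in pairs:
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            tp += 1
    return _score_from_counts(n_t, n_d, tp)


def combine_scores(scores: Sequence[DetectionScore]) -> DetectionScore:
    """Pool per-field scores by summing matches, detections and truths."""
    n_t = sum(s.n_truth for s in scores)
    n_d = sum(s.n_detected for s in scores)
    tp = sum(s.true_positives for s in scores)
    return _score_from_counts(n_t, n_d, tp)


def simulate_fields(params: SceneParams, n_fields: int, seed: int,
                    out_dir, prefix: str = "field") -> list[dict]:
    """Render ``n_fields`` independent fields to OME-TIFF + truth JSON.

    A single global seed feeds a hierarchical per-field substream, so
    batches are reproducible while fields stay independent. Returns one
    record per field: field_id, stack path, truth path.
    """
    from .io import write_stack

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_fields) % (2 ** 31)
    records = []
    for i in range(n_fields):
        fid = f"{prefix}_{i:03d}"
        scene = generate_scene(params, int(child_seeds[i]), field_id=fid)
        stack = render_stack(scene)
        stack_path = out_dir / f"{fid}.ome.tif"
        truth_path = out_dir / f"{fid}.truth.json"
        write_stack(stack, stack_path)
        scene.write_truth(truth_path)
        records.append({"field_id": fid, "stack": stack_path,
                        "truth": truth_path, "scene": scene})
    return records


def scene_params_from_dict(d: dict) -> SceneParams:
    """Build SceneParams from a plain dict (e.g. parsed sim.yaml), strictly."""
    known = {f for f in SceneParams.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise InputError(f"unknown scene parameter(s): {sorted(unknown)}")
    tup_keys = {"cell_axis_um", "nucleus_axis_um", "mp_diameter_um",
                "mp_annulus", "confounder_diameter_um"}
    clean = {k: (tuple(v) if k in tup_keys else v) for k, v in d.items()}
    return SceneParams(**clean)
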