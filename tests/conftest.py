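import math

import numpy as np
import pytest

from macroquant.io import CalibratedStack, ChannelImage
from macroquant.preprocess import ProjectedImage
from macroquant.segmentation import BinaryMask
from macroquant.synthetic import Cell, SceneParams, Structure, SyntheticScene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_channel(pixels, pixel_size=0.3, role="dextran", bit_depth=8):
    return ChannelImage(pixels=np.asarray(pixels), pixel_size=pixel_size,
                        role=role, bit_depth=bit_depth)


def make_projected(pixels, pixel_size=0.3, role="dextran"):
    return ProjectedImage(pixels=np.asarray(pixels, dtype=np.uint8),
                          pixel_size=pixel_size, role=role)


def make_mask(pixels, pixel_size=0.3, role="dextran", threshold=0):
    return BinaryMask(pixels=np.asarray(pixels, dtype=bool),
                      pixel_size=pixel_size, source_role=role,
                      threshold_used=threshold)


def small_scene_params(**overrides) -> SceneParams:
    """Desk-scale scene defaults for fast tests."""
    base = dict(field_size_px=256)
    base.update(overrides)
    return SceneParams(**base)


def handcrafted_scene(n_cells_x=4, n_cells_y=2, mp_per_cell=None,
                      snr=50.0, field_size_px=256) -> SyntheticScene:
    """A fully deterministic scene: a grid of identical cells with
    hand-placed, well-separated, comfortably in-range macropinosomes."""
    params = SceneParams(field_size_px=field_size_px, snr=snr,
                         background_gradient=20.0, noise=False)
    field = params.field_size_um  # 76.8 um at the default 256 px
    cells = []
    structures = []
    step_x = field / n_cells_x
    step_y = field / n_cells_y
    mp_offsets = mp_per_cell if mp_per_cell is not None else [
        (-4.5, 0.0, 1.6), (4.5, 0.0, 2.4), (0.0, 4.5, 3.0)]
    ci = 0
    for iy in range(n_cells_y):
        for ix in range(n_cells_x):
            cx = (ix + 0.5) * step_x
            cy = (iy + 0.5) * step_y
            cells.append(Cell(
                center_um=(cx, cy), semi_axes_um=(7.0, 6.5), angle_rad=0.0,
                gfp_positive=(ix % 2 == 0),
                nucleus_center_um=(cx, cy), nucleus_semi_axes_um=(2.6, 2.2)))
            for dx, dy, d in mp_offsets:
                structures.append(Structure(
                    cls="macropinosome", x_um=cx + dx, y_um=cy + dy,
                    z_um=2.5, diameter_um=d, cell_index=ci))
            ci += 1
    return SyntheticScene(field_id="handcrafted", params=params, seed=0,
                          cells=cells, structures=structures)
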