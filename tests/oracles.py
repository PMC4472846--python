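"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — direct sweeps and breadth-first
search — and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labelling by explicit breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or labels[sy, sx]:
                continue
            current += 1
            queue = deque([(sy, sx)])
            labels[sy, sx] = current
            while queue:
                y, x = queue.popleft()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and not labels[ny, nx]):
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels, current


def otsu_exhaustive(image: np.ndarray) -> int:
    """Otsu level by exhaustive search of between-class variance over 0-255."""
    counts = np.bincount(np.asarray(image).ravel(), minlength=256).astype(float)
    total = counts.sum()
    levels = np.arange(256, dtype=float)
    best_level, best_var = 0, -1.0
    for t in range(256):
        w0 = counts[:t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[:t + 1] * counts[:t + 1]).sum() / w0
        mu1 = (levels[t + 1:] * counts[t + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_level = var, t
    return best_level


def rolling_ball_background_sweep(image: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background by direct min-then-max sweeps with the ball
    height profile, reflect-padded at the borders."""
    image = np.asarray(image, dtype=float)
    r = int(radius)
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= r * r:
                offsets.append((dy, dx, math.sqrt(r * r - d2)))
    # pad by 2r so every read below stays inside the padded frame
    padded = np.pad(image, 2 * r, mode="reflect")
    h, w = image.shape
    eroded = np.full(padded.shape, np.inf)
    for y in range(r, h + 3 * r):
        for x in range(r, w + 3 * r):
            eroded[y, x] = min(padded[y + dy, x + dx] - hh
                               for dy, dx, hh in offsets)
    opened = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            py, px = y + 2 * r, x + 2 * r
            opened[y, x] = max(eroded[py + dy, px + dx] + hh
                               for dy, dx, hh in offsets)
    return opened


def max_project_bruteforce(slices: list[np.ndarray]) -> np.ndarray:
    """Per-pixel maximum over slices by explicit iteration."""
    out = np.array(slices[0], dtype=float)
    h, w = out.shape
    for sl in slices[1:]:
        for y in range(h):
            for x in range(w):
                if sl[y, x] > out[y, x]:
                    out[y, x] = sl[y, x]
    return out
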