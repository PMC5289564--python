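"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first principles
(flood fill, all-pairs distances, angle sweeps, shoelace hulls) so the
implementation under test is checked against an independent route.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from tunasonar.segment import Blob


# ---------------------------------------------------------------------------
# oracles


def flood_fill_partition(mask: np.ndarray) -> set[frozenset]:
    """8-connected components of a boolean mask by breadth-first search."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = set()
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = []
                q = deque([(y, x)])
                seen[y, x] = True
                while q:
                    cy, cx = q.popleft()
                    comp.append((cx, cy))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < h and 0 <= nx < w and \
                                    mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                q.append((ny, nx))
                comps.add(frozenset(comp))
    return comps


def feret_all_pairs(pixels: np.ndarray) -> float:
    """O(n^2) maximum pairwise distance between pixel centres."""
    pts = pixels.astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return math.sqrt(float(d2.max()))


def minferet_angle_sweep(pixels: np.ndarray, step_deg: float = 0.1) -> float:
    """Minimum caliper width of the pixel centres by angle sweep (coarse
    0.1-degree grid, then local refinement around the coarse minimum so
    discretisation error is negligible), floored at 1 px."""
    pts = pixels.astype(float)

    def width(ang_deg: float) -> float:
        t = math.radians(ang_deg)
        proj = pts @ np.array([math.cos(t), math.sin(t)])
        return float(proj.max() - proj.min())

    grid = np.arange(0.0, 180.0, step_deg)
    widths = [width(a) for a in grid]
    a0 = grid[int(np.argmin(widths))]
    fine = np.arange(a0 - step_deg, a0 + step_deg, step_deg / 100.0)
    best = min(min(widths), min(width(a) for a in fine))
    return max(best, 1.0)


def hull_area_shoelace(points: np.ndarray) -> float:
    """Convex-hull area via Andrew's monotone chain + shoelace formula."""
    pts = sorted(set(map(tuple, points.tolist())))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for (x0, y0), (x1, y1) in zip(hull, hull[1:] + hull[:1]):
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


# ---------------------------------------------------------------------------
# shape builders


def blob_from_mask(mask: np.ndarray, blob_id: str = "b") -> Blob:
    ys, xs = np.nonzero(mask)
    return Blob(np.column_stack([xs, ys]), blob_id)


def filled_rect(w: int, h: int) -> Blob:
    return blob_from_mask(np.ones((h, w), dtype=bool))


def filled_disk(radius: int) -> Blob:
    n = radius + 2
    ys, xs = np.mgrid[-n:n + 1, -n:n + 1]
    return blob_from_mask(xs ** 2 + ys ** 2 <= radius ** 2)


def rasterized_ellipse(a: float, b: float, angle_deg: float,
                       size: int | None = None) -> Blob:
    """Filled ellipse with semi-axes a >= b at the given CCW angle
    (y-down raster, consistent with the package convention)."""
    size = size or int(2 * a + 8)
    c = size / 2
    ys, xs = np.mgrid[0:size, 0:size]
    t = math.radians(angle_deg)
    dx, dy = xs - c, ys - c
    u = dx * math.cos(t) - dy * math.sin(t)
    v = -(dx * math.sin(t) + dy * math.cos(t))
    return blob_from_mask((u / a) ** 2 + (v / b) ** 2 <= 1.0)


def random_blob(rng: np.random.Generator, max_extent: int = 30) -> Blob:
    """A random connected blob: union of 1-3 overlapping ellipses/boxes,
    largest connected component taken."""
    from scipy import ndimage

    size = max_extent + 10
    mask = np.zeros((size, size), dtype=bool)
    cx0, cy0 = size / 2, size / 2
    for i in range(int(rng.integers(1, 4))):
        a = float(rng.uniform(1.5, max_extent / 2))
        b = float(rng.uniform(1.0, a))
        t = math.radians(float(rng.uniform(0, 180)))
        cx = cx0 + float(rng.uniform(-3, 3)) * (i > 0)
        cy = cy0 + float(rng.uniform(-3, 3)) * (i > 0)
        ys, xs = np.mgrid[0:size, 0:size]
        u = (xs - cx) * math.cos(t) - (ys - cy) * math.sin(t)
        v = (xs - cx) * math.sin(t) + (ys - cy) * math.cos(t)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        mask[size // 2, size // 2] = True
        return blob_from_mask(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return blob_from_mask(labels == (int(np.argmax(sizes)) + 1))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_table():
    """A modest separable feature table shared by evaluation tests."""
    from tunasonar.synthgen import make_feature_table

    return make_feature_table(60, 140, seed=42)


@pytest.fixture(scope="session")
def rendered_scene():
    """One rendered noisy scene with tuna and clutter, plus its config."""
    from tunasonar import synthgen as sg

    cfg = sg.SceneConfig(surface_noise_level=0.3, seed=11)
    tuna = sg.sample_blob_specs(sg.TUNA, 2, seed=11, config=cfg)
    clut = sg.sample_blob_specs(sg.NO_TUNA, 3, seed=12, config=cfg,
                                existing=tuna)
    image, gt = sg.render_scene(cfg, tuna + clut)
    return cfg, tuna + clut, image, gt
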