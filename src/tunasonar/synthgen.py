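"""Synthetic sonar-scene generator.

Emulates the screen dumps of an analog omni-directional medium-range sonar
well enough to exercise every downstream stage with known ground truth:
a circular echogram on a black or blue background, overlay graphics (range
circumferences, a cursor cross, a vessel track) drawn from a dedicated
palette, surface-noise speckle near the disc rim, a menu panel with
non-echogram content, and echo blobs rendered as filled rotated ellipses.

Tuna-like blobs are large, elongated and near-horizontal; clutter blobs
are small and rounder with no preferred orientation.  The class-conditional
distributions are configurable; the defaults give a cleanly separable
regime (tuna area 1500-8000 px with aspect ratio 2-5, clutter 100-600 px
with aspect ratio 1-2) and respect the 415-px smallest school observed in
the reference imagery.

All randomness flows through one seeded NumPy generator per call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import (NEGATIVE_CLASS, POSITIVE_CLASS, TABLE_COLUMNS,
                      TrainingTable)
from .preprocess import SonarFrame, SonarLayout

log = logging.getLogger(__name__)

TUNA = POSITIVE_CLASS
NO_TUNA = NEGATIVE_CLASS

#: Colours reserved for overlay graphics; disjoint from blob colours so the
#: ground truth is unambiguous (real-image ambiguity is a preprocessing
#: concern, not a generator one).
DEFAULT_OVERLAY_PALETTE = [(0, 255, 0), (255, 255, 255), (0, 220, 220)]

#: Echo colours used for blobs and surface speckle (warm sonar palette).
BLOB_COLORS = [(200, 40, 40), (230, 130, 30), (240, 210, 50)]

BACKGROUND_RGB = {"black": (0, 0, 0), "blue": (0, 0, 140)}


@dataclass
class SceneConfig:
    """Geometry and rendering options for one synthetic sonar screen."""

    image_width: int = 640
    image_height: int = 480
    echogram_center: tuple[int, int] = (235, 240)
    echogram_radius: int = 220
    background_style: str = "black"
    menu_panel_box: tuple[int, int, int, int] = (470, 10, 630, 470)
    overlay_palette: list = field(
        default_factory=lambda: list(DEFAULT_OVERLAY_PALETTE))
    n_range_rings: int = 3
    surface_noise_level: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        cx, cy = self.echogram_center
        r = self.echogram_radius
        if not (0 <= cx - r and cx + r < self.image_width
                and 0 <= cy - r and cy + r < self.image_height):
            raise ValueError("echogram disc does not fit inside image bounds")
        x0, y0, x1, y1 = self.menu_panel_box
        if x0 <= cx + r and x1 > cx - r and y0 <= cy + r and y1 > cy - r:
            raise ValueError("menu panel box overlaps the echogram disc")
        if not 0.0 <= self.surface_noise_level <= 1.0:
            raise ValueError("surface_noise_level must be in [0, 1]")
        if self.background_style not in BACKGROUND_RGB:
            raise ValueError(f"unknown background style {self.background_style!r}")

    def layout(self) -> SonarLayout:
        return SonarLayout(self.echogram_center, self.echogram_radius,
                           self.menu_panel_box)


@dataclass
class BlobSpec:
    """Specification of one rendered echo blob (a filled rotated ellipse)."""

    class_label: str
    target_area: float  # pixels
    aspect_ratio: float  # >= 1
    orientation_deg: float  # [0, 180), CCW from +x (y flipped)
    center: tuple[float, float]
    fill_color: tuple[int, int, int] = BLOB_COLORS[0]

    def __post_init__(self) -> None:
        if self.target_area < 1:
            raise ValueError("target_area must be >= 1")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")

    @property
    def semi_axes(self) -> tuple[float, float]:
        a = math.sqrt(self.target_area * self.aspect_ratio / math.pi)
        return a, a / self.aspect_ratio


@dataclass
class GroundTruth:
    """Per-pixel instance labels plus per-blob and image-level truth."""

    labels: np.ndarray  # (H, W) int32; 0 = not a blob pixel
    blobs: list  # list of (blob_id, class_label, BlobSpec)
    image_label: str  # "tuna" iff at least one tuna blob
    seed: int = 0

    def pixel_count(self, blob_index: int) -> int:
        return int((self.labels == blob_index + 1).sum())


@dataclass
class MorphologyParams:
    """Class-conditional blob morphology: uniform area and aspect-ratio
    ranges, plus an orientation regime (``"horizontal"`` = wrapped normal
    around 0/180 deg with ``orientation_std_deg``; ``"uniform"`` = uniform
    on [0, 180))."""

    area_range: tuple[float, float]
    ar_range: tuple[float, float]
    orientation: str = "uniform"
    orientation_std_deg: float = 12.0

    @property
    def mean_area(self) -> float:
        return 0.5 * (self.area_range[0] + self.area_range[1])

    @property
    def mean_ar(self) -> float:
        return 0.5 * (self.ar_range[0] + self.ar_range[1])


DEFAULT_TUNA_PARAMS = MorphologyParams((1500.0, 8000.0), (2.0, 5.0),
                                       "horizontal", 12.0)
DEFAULT_CLUTTER_PARAMS = MorphologyParams((100.0, 600.0), (1.0, 2.0), "uniform")


# ---------------------------------------------------------------------------
# spec sampling


def _ellipse_extents(a: float, b: float, theta_deg: float) -> tuple[float, float]:
    t = math.radians(theta_deg)
    ex = math.sqrt((a * math.cos(t)) ** 2 + (b * math.sin(t)) ** 2)
    ey = math.sqrt((a * math.sin(t)) ** 2 + (b * math.cos(t)) ** 2)
    return ex, ey


def sample_blob_specs(class_label: str, n: int,
                      morphology_params: MorphologyParams | None = None,
                      seed: int | None = None,
                      config: SceneConfig | None = None,
                      upper_half_only: bool = True,
                      avoid_rim_fraction: float = 0.82,
                      avoid_overlap: bool = True,
                      existing: list | None = None) -> list[BlobSpec]:
    """Draw ``n`` i.i.d. blob specs for one class.

    Centres are rejection-sampled so each ellipse fits inside the echogram
    disc (by default inside its upper half, clear of the surface-noise rim)
    and, with ``avoid_overlap`` (the default), does not collide with other
    sampled specs or those in ``existing``.  For statistics-only sampling
    of many specs (no rendering) pass ``avoid_overlap=False``; only a
    handful of disjoint blobs fit in one upper half-disc.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if morphology_params is None:
        morphology_params = (DEFAULT_TUNA_PARAMS if class_label == TUNA
                             else DEFAULT_CLUTTER_PARAMS)
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    cx0, cy0 = config.echogram_center
    R = config.echogram_radius * avoid_rim_fraction

    placed = list(existing or [])
    out: list[BlobSpec] = []

    def try_place(a, b, theta):
        """Rejection-sample a centre for this ellipse; None if none fits."""
        for _ in range(300):
            ang = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.random()) * max(R - a - 2.0, 1.0)
            cx = cx0 + rad * math.cos(ang)
            cy = cy0 + rad * math.sin(ang)
            ex, ey = _ellipse_extents(a, b, theta)
            if upper_half_only and cy + ey > cy0 - 2:
                continue
            if math.hypot(cx - cx0, cy - cy0) + a > R:
                continue
            ok = True
            for other in (placed + out) if avoid_overlap else []:
                oa, ob = other.semi_axes
                oex, oey = _ellipse_extents(oa, ob, other.orientation_deg)
                if (abs(cx - other.center[0]) < ex + oex + 4.0
                        and abs(cy - other.center[1]) < ey + oey + 4.0):
                    ok = False
                    break
            if ok:
                return cx, cy
        return None

    for _ in range(n):
        for _redraw in range(20):  # redraw morphology if placement fails
            area = rng.uniform(*morphology_params.area_range)
            ar = rng.uniform(*morphology_params.ar_range)
            if morphology_params.orientation == "horizontal":
                theta = (rng.normal(0.0,
                                    morphology_params.orientation_std_deg)
                         % 180.0)
            else:
                theta = rng.uniform(0.0, 180.0)
            a = math.sqrt(area * ar / math.pi)
            b = a / ar
            color = BLOB_COLORS[int(rng.integers(len(BLOB_COLORS)))]
            center = try_place(a, b, theta)
            if center is not None:
                break
        else:
            raise RuntimeError(
                f"could not place a {class_label} blob inside the echogram; "
                "reduce blob count or size")
        out.append(BlobSpec(class_label, area, ar, theta, center, color))
    return out


# ---------------------------------------------------------------------------
# rendering


def _fill_ellipse(canvas: np.ndarray, labels: np.ndarray, spec: BlobSpec,
                  label_value: int, roughen_rng=None) -> None:
    a, b = spec.semi_axes
    t = math.radians(spec.orientation_deg)
    cx, cy = spec.center
    ex, ey = _ellipse_extents(a, b, spec.orientation_deg)
    x0 = max(int(math.floor(cx - ex - 1)), 0)
    x1 = min(int(math.ceil(cx + ex + 1)), canvas.shape[1] - 1)
    y0 = max(int(math.floor(cy - ey - 1)), 0)
    y1 = min(int(math.ceil(cy + ey + 1)), canvas.shape[0] - 1)
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    dx = xs - cx
    dy = ys - cy
    # y flipped: orientation_deg is CCW from +x in display coordinates
    u = dx * math.cos(t) - dy * math.sin(t)
    v = -(dx * math.sin(t) + dy * math.cos(t))
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[y0:y1 + 1, x0:x1 + 1][inside] = spec.fill_color
    labels[y0:y1 + 1, x0:x1 + 1][inside] = label_value


def _draw_ring(canvas: np.ndarray, center, radius: float, color) -> None:
    from skimage.draw import circle_perimeter

    rr, cc = circle_perimeter(int(round(center[1])), int(round(center[0])),
                              int(round(radius)), shape=canvas.shape[:2])
    canvas[rr, cc] = color


def _draw_line(canvas: np.ndarray, p0, p1, color) -> None:
    from skimage.draw import line

    rr, cc = line(int(round(p0[1])), int(round(p0[0])),
                  int(round(p1[1])), int(round(p1[0])))
    ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
    canvas[rr[ok], cc[ok]] = color


def render_scene(config: SceneConfig,
                 blob_specs: list[BlobSpec]) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic sonar screen and its ground truth.

    Overlays and speckle are drawn first and blobs on top, so the ground
    truth raster (which marks blob pixels only) is exact.  The same config,
    specs and seed always produce a bit-identical image.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cx, cy = config.echogram_center
    r = config.echogram_radius
    h, w = config.image_height, config.image_width

    for i, spec in enumerate(blob_specs):
        a = spec.semi_axes[0]
        d = math.hypot(spec.center[0] - cx, spec.center[1] - cy)
        if d + a > r:
            raise ValueError(
                f"blob spec {i} (center={spec.center}, max extent {a:.1f}) "
                "does not fit inside the echogram disc")

    canvas = np.full((h, w, 3), 25, dtype=np.uint8)  # bezel grey
    ys, xs = np.mgrid[0:h, 0:w]
    disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r
    canvas[disc] = BACKGROUND_RGB[config.background_style]

    # menu panel: title bar plus text-like lines
    x0, y0, x1, y1 = config.menu_panel_box
    canvas[y0:y1, x0:x1] = (40, 40, 60)
    for row in range(y0 + 8, y1 - 8, 14):
        width = int(rng.integers((x1 - x0) // 3, x1 - x0 - 10))
        canvas[row:row + 4, x0 + 5:x0 + 5 + width] = (170, 170, 170)

    palette = [tuple(c) for c in config.overlay_palette]
    ring_color = palette[0]
    cross_color = palette[min(1, len(palette) - 1)]
    track_color = palette[min(2, len(palette) - 1)]

    # range circumferences
    for k in range(1, config.n_range_rings + 1):
        _draw_ring(canvas, (cx, cy), r * k / (config.n_range_rings + 0.15),
                   ring_color)
    # cursor cross through the centre
    _draw_line(canvas, (cx - r, cy), (cx + r, cy), cross_color)
    _draw_line(canvas, (cx, cy - r), (cx, cy + r), cross_color)
    # vessel track: a short jittered polyline from the centre
    ang = rng.uniform(0, 2 * math.pi)
    pts = [(cx, cy)]
    for _ in range(4):
        ang += rng.normal(0, 0.3)
        step = 0.18 * r
        px, py = pts[-1]
        pts.append((px + step * math.cos(ang), py + step * math.sin(ang)))
    for p0, p1 in zip(pts, pts[1:]):
        if math.hypot(p1[0] - cx, p1[1] - cy) < r - 2:
            _draw_line(canvas, p0, p1, track_color)

    # surface-noise speckle: short arcs in the outer 15% of the radius,
    # laid out on a jittered angular grid so arcs never merge
    if config.surface_noise_level > 0:
        n_speck = int(round(config.surface_noise_level * 150))
        if n_speck:
            slots = np.linspace(0, 2 * math.pi, n_speck, endpoint=False)
            for base in slots:
                theta0 = base + rng.uniform(0, 0.25 * 2 * math.pi / n_speck)
                rad = rng.uniform(0.87, 0.97) * r
                arc_len = int(rng.integers(3, 7))
                color = BLOB_COLORS[int(rng.integers(len(BLOB_COLORS)))]
                for j in range(arc_len):
                    th = theta0 + j / rad
                    px = int(round(cx + rad * math.cos(th)))
                    py = int(round(cy + rad * math.sin(th)))
                    if 0 <= px < w and 0 <= py < h:
                        canvas[py, px] = color

    labels = np.zeros((h, w), dtype=np.int32)
    entries = []
    for i, spec in enumerate(blob_specs):
        _fill_ellipse(canvas, labels, spec, i + 1)
        entries.append((f"synth{config.seed:06d}_{i:03d}", spec.class_label,
                        spec))

    image_label = TUNA if any(s.class_label == TUNA for s in blob_specs) \
        else NO_TUNA
    return canvas, GroundTruth(labels, entries, image_label, config.seed)


def make_frame(config: SceneConfig, image: np.ndarray,
               frame_id: str = "") -> SonarFrame:
    """Wrap a rendered image as a SonarFrame for the preprocessing stage."""
    return SonarFrame(
        raster=image, layout=config.layout(), frame_id=frame_id,
        overlay_palette=[tuple(c) for c in config.overlay_palette],
        background_style=config.background_style,
    )


# ---------------------------------------------------------------------------
# direct feature-table synthesis (bypasses rendering)


def make_feature_table(n_tuna: int, n_clutter: int,
                       tuna_params: MorphologyParams | None = None,
                       clutter_params: MorphologyParams | None = None,
                       seed: int | None = None) -> TrainingTable:
    """Emit an S1-schema feature table directly from the class-conditional
    morphology distributions, without rendering any image.

    Every row satisfies the descriptor invariants (AR = Major/Minor >= 1,
    Roundness = 1/AR, MinFeret <= Feret, Width*Height >= Area,
    Solidity in (0, 1]); descriptors are mutually consistent up to small
    multiplicative noise, mimicking rasterisation error.
    """
    if n_tuna < 0 or n_clutter < 0:
        raise ValueError("row counts must be >= 0")
    tuna_params = tuna_params or DEFAULT_TUNA_PARAMS
    clutter_params = clutter_params or DEFAULT_CLUTTER_PARAMS
    rng = np.random.default_rng(seed)

    def rows_for(n: int, params: MorphologyParams, label: str, start: int):
        recs = []
        for i in range(n):
            area = rng.uniform(*params.area_range)
            ar = rng.uniform(*params.ar_range)
            if params.orientation == "horizontal":
                theta = rng.normal(0.0, params.orientation_std_deg) % 180.0
            else:
                theta = rng.uniform(0.0, 180.0)
            major = 2.0 * math.sqrt(area * ar / math.pi)
            minor = major / ar
            a, b = major / 2.0, minor / 2.0
            # Ramanujan approximation of the ellipse circumference
            perim = math.pi * (3 * (a + b)
                               - math.sqrt((3 * a + b) * (a + 3 * b)))
            perim *= 1.0 + abs(rng.normal(0, 0.02))
            circ = min(4.0 * math.pi * area / perim ** 2, 1.0)
            feret = major * (1.0 + abs(rng.normal(0, 0.015)))
            minferet = max(min(minor * (1.0 + abs(rng.normal(0, 0.02))),
                               feret), 1.0)
            ex, ey = _ellipse_extents(a, b, theta)
            width = max(2.0 * ex, 1.0) * (1.0 + abs(rng.normal(0, 0.01)))
            height = max(2.0 * ey, 1.0) * (1.0 + abs(rng.normal(0, 0.01)))
            if width * height < area:  # safety: bbox must contain the blob
                scale = math.sqrt(area / (width * height)) * 1.001
                width *= scale
                height *= scale
            x = rng.uniform(60, 380)
            y = rng.uniform(60, 200)
            fangle = (theta + rng.normal(0, 1.0)) % 180.0
            t = math.radians(fangle)
            e0 = (x - feret / 2 * math.cos(t), y + feret / 2 * math.sin(t))
            e1 = (x + feret / 2 * math.cos(t), y - feret / 2 * math.sin(t))
            fx, fy = e0 if (e0[1], e0[0]) <= (e1[1], e1[0]) else e1
            sol = float(np.clip(rng.normal(0.93 if label == TUNA else 0.86,
                                           0.03), 0.55, 1.0))
            recs.append({
                "Blob_ID": f"SYN{2009 if label == TUNA else 2011}"
                           f"T{start + i:06d}",
                "Area": area, "Perimeter": perim,
                "BX": x - width / 2, "BY": y - height / 2,
                "Width": width, "Height": height, "X": x, "Y": y,
                "Major": major, "Minor": minor, "Angle": theta,
                "Circularity": circ, "Feret": feret,
                "FeretX": fx, "FeretY": fy, "FeretAngle": fangle,
                "MinFeret": minferet, "AR": ar, "Roundness": 1.0 / ar,
                "Solidity": sol, "Class": label,
            })
        return recs

    records = rows_for(n_tuna, tuna_params, TUNA, 0)
    records += rows_for(n_clutter, clutter_params, NO_TUNA, n_tuna)
    if records:
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in TABLE_COLUMNS})
        df["Blob_ID"] = df["Blob_ID"].astype(str)
        df["Class"] = df["Class"].astype(str)
    return TrainingTable(df)
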