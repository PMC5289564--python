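"""Pre-processing of raw sonar screenshots.

A medium-range-sonar screen dump has two regions: the circular echogram
display and the menu panel.  Pre-processing splits them apart, removes the
display overlays (range circumferences, cursor crosses, vessel tracks),
suppresses surface-noise speckle, and restricts the echogram to its upper
half — tuna schools are not reliably visible in the lower half because of
the vessel's wake, and schools appear first ahead of the (faster-moving)
vessel, which the display places at the top of the screen.

Cleaning order is: overlays -> noise -> upper-half mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .segment import EIGHT_CONN, DEFAULT_RGB_TOL, _match_colors, dominant_color

log = logging.getLogger(__name__)

DEFAULT_MAX_LINE_THICKNESS = 2
DEFAULT_SPECKLE_MAX_AREA = 8


@dataclass
class SonarLayout:
    """Screen geometry of one sonar model (from a layout config, not OCR)."""

    echogram_center: tuple[int, int]  # (x, y)
    echogram_radius: int
    menu_panel_box: tuple[int, int, int, int]  # (x0, y0, x1, y1), exclusive


@dataclass
class SonarFrame:
    """A raw sonar screenshot plus its layout metadata."""

    raster: np.ndarray  # (H, W, 3) uint8
    layout: SonarLayout
    frame_id: str = ""
    overlay_palette: list = field(default_factory=list)  # list of RGB triples
    background_style: str = "black"  # hint only


@dataclass
class EchogramRegion:
    """The echogram raster (cropped to the disc bounding box) plus a mask of
    the pixels currently considered operative."""

    raster: np.ndarray
    valid_mask: np.ndarray
    center: tuple[float, float]  # disc centre in region coordinates
    radius: int
    origin: tuple[int, int] = (0, 0)  # (x0, y0) of the crop in frame coords
    background_color: np.ndarray | None = None

    def bg(self) -> np.ndarray:
        if self.background_color is None:
            self.background_color = dominant_color(self.raster, self.valid_mask)
        return self.background_color


def _disc_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2


def split_regions(frame: SonarFrame) -> tuple[EchogramRegion, np.ndarray]:
    """Split a frame into the echogram disc region and the menu raster.

    The echogram raster covers exactly the disc bounding box; the menu
    raster covers the menu panel box.  The two boxes must lie inside the
    image and be disjoint.
    """
    h, w = frame.raster.shape[:2]
    cx, cy = frame.layout.echogram_center
    r = frame.layout.echogram_radius
    if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
        raise ValueError(
            f"echogram disc (center=({cx},{cy}), radius={r}) exceeds image "
            f"bounds {w}x{h}"
        )
    x0, y0, x1, y1 = frame.layout.menu_panel_box
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(
            f"menu panel box {frame.layout.menu_panel_box} exceeds image "
            f"bounds {w}x{h}"
        )
    if x0 <= cx + r and x1 > cx - r and y0 <= cy + r and y1 > cy - r:
        raise ValueError(
            f"menu panel box {frame.layout.menu_panel_box} overlaps the "
            f"echogram disc bounding box"
        )
    ex0, ey0 = cx - r, cy - r
    crop = frame.raster[ey0:cy + r + 1, ex0:cx + r + 1].copy()
    valid = _disc_mask(crop.shape[:2], (cx - ex0, cy - ey0), r)
    region = EchogramRegion(
        raster=crop, valid_mask=valid, center=(float(cx - ex0), float(cy - ey0)),
        radius=r, origin=(ex0, ey0),
    )
    menu = frame.raster[y0:y1, x0:x1].copy()
    return region, menu


def mask_upper_half(region: EchogramRegion) -> EchogramRegion:
    """Restrict the valid mask to the upper half-disc (y <= centre y)."""
    ys = np.arange(region.raster.shape[0])[:, None]
    upper = ys <= region.center[1]
    disc = _disc_mask(region.raster.shape[:2], region.center, region.radius)
    return replace(region, valid_mask=region.valid_mask & upper & disc)


def remove_overlays(region: EchogramRegion, overlay_palette,
                    max_line_thickness: int = DEFAULT_MAX_LINE_THICKNESS,
                    tol: int = DEFAULT_RGB_TOL) -> EchogramRegion:
    """Erase display overlays (rings, crosses, tracks) from the echogram.

    Pixels matching an overlay colour (within an RGB tolerance) are set to
    the background colour.  Remaining thin structures of width up to
    ``max_line_thickness`` are removed by a morphological opening of the
    foreground mask, and blob bodies cut by a removed line are reconnected
    by a closing with the same structuring element (the open-close filter
    is idempotent).  Reconnected pixels are painted with the colour of the
    nearest surviving foreground pixel.
    """
    palette = np.atleast_2d(np.asarray(overlay_palette, dtype=np.int16))
    if palette.size == 0:
        raise ValueError("overlay palette must be non-empty")
    raster = region.raster.copy()
    valid = region.valid_mask
    bg = region.bg()

    overlay = _match_colors(raster, palette, tol) & valid
    raster[overlay] = bg

    fg = ~_match_colors(raster, bg[None, :].astype(np.int16), tol) & valid
    size = max_line_thickness + 1
    struct = np.ones((size, size), dtype=bool)
    opened = ndimage.binary_opening(fg, structure=struct)
    closed = ndimage.binary_closing(opened, structure=struct) & valid

    out = raster.copy()
    out[fg & ~closed] = bg
    filled = closed & ~(fg & closed)
    if filled.any():
        survivors = fg & closed
        if survivors.any():
            _, (iy, ix) = ndimage.distance_transform_edt(
                ~survivors, return_indices=True)
            out[filled] = raster[iy[filled], ix[filled]]
        else:
            out[filled] = bg
    return replace(region, raster=out, background_color=bg)


def suppress_noise(region: EchogramRegion,
                   speckle_max_area: int = DEFAULT_SPECKLE_MAX_AREA,
                   tol: int = DEFAULT_RGB_TOL) -> EchogramRegion:
    """Remove isolated foreground components smaller than ``speckle_max_area``
    pixels (strictly smaller; 0 is the identity)."""
    if speckle_max_area < 0:
        raise ValueError("speckle_max_area must be >= 0")
    if speckle_max_area == 0:
        return region
    raster = region.raster.copy()
    bg = region.bg()
    fg = ~_match_colors(raster, bg[None, :].astype(np.int16), tol) & region.valid_mask
    labels, n = ndimage.label(fg, structure=EIGHT_CONN)
    if n:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < speckle_max_area) + 1
        if len(small):
            raster[np.isin(labels, small)] = bg
    return replace(region, raster=raster, background_color=bg)


def clean_frame(frame: SonarFrame,
                max_line_thickness: int = DEFAULT_MAX_LINE_THICKNESS,
                speckle_max_area: int = DEFAULT_SPECKLE_MAX_AREA,
                tol: int = DEFAULT_RGB_TOL) -> EchogramRegion:
    """Full pre-processing chain: split -> overlays -> noise -> upper half."""
    region, _ = split_regions(frame)
    if frame.overlay_palette:
        region = remove_overlays(region, frame.overlay_palette,
                                 max_line_thickness, tol)
    region = suppress_noise(region, speckle_max_area, tol)
    return mask_upper_half(region)
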