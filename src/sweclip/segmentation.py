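"""Locate the elastogram box in a frame and calibrate the physical scale.

Exported SWE clips surround the elastogram with a colored frame line —
orange in video exports, white in single-image exports. Automatic
segmentation finds that ring and returns its interior; when it fails (or the
layout differs) the user supplies the box and the mm-per-pixel scale
manually. The scale is otherwise read from the measurement bar (ruler) by
measuring the pixel spacing of its tick marks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

__all__ = [
    "FrameImage",
    "ElastogramGeometry",
    "SegmentationError",
    "ScaleDetectionError",
    "detect_elastogram_box",
    "detect_scale",
    "manual_geometry",
    "auto_geometry",
]


class SegmentationError(RuntimeError):
    """Automatic elastogram detection failed; manual segmentation required."""


class ScaleDetectionError(RuntimeError):
    """Measurement-bar analysis failed; supply mm_per_px manually."""


@dataclass
class FrameImage:
    """One RGB frame of a clip: the raw pixel substrate."""

    pixels: np.ndarray  # (H, W, 3) uint8
    index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("frame pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("frames must be at least 32x32 pixels")
        if self.pixels.dtype != np.uint8:
            self.pixels = self.pixels.astype(np.uint8)
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ElastogramGeometry:
    """Elastogram bounding box and physical scale.

    ``box`` is a half-open pixel rectangle ``(row_start, row_stop,
    col_start, col_stop)``; ``mm_per_px`` converts pixels to millimetres.
    """

    box: tuple
    mm_per_px: float
    mode: str = "auto"

    def __post_init__(self):
        r0, r1, c0, c1 = (int(v) for v in self.box)
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"degenerate box {self.box}")
        if r0 < 0 or c0 < 0:
            raise ValueError(f"box {self.box} has negative coordinates")
        self.box = (r0, r1, c0, c1)
        if not np.isfinite(self.mm_per_px) or self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive and finite")
        if self.mode not in ("auto", "manual"):
            raise ValueError("mode must be 'auto' or 'manual'")

    @property
    def height_px(self) -> int:
        return self.box[1] - self.box[0]

    @property
    def width_px(self) -> int:
        return self.box[3] - self.box[2]

    @property
    def height_mm(self) -> float:
        return self.height_px * self.mm_per_px

    @property
    def width_mm(self) -> float:
        return self.width_px * self.mm_per_px


# Default matchers: far from both grayscale B-mode and blended colormap hues.
def _orange_mask(px: np.ndarray) -> np.ndarray:
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    return (r >= 200) & (g >= 80) & (g <= 180) & (b <= 80)


def _white_mask(px: np.ndarray) -> np.ndarray:
    return np.all(px >= 245, axis=-1)


def _custom_mask(px: np.ndarray, center, tol) -> np.ndarray:
    diff = np.abs(px.astype(int) - np.asarray(center, dtype=int))
    return np.all(diff <= tol, axis=-1)


def _line_mask(pixels: np.ndarray, frame_line_color) -> np.ndarray:
    if isinstance(frame_line_color, str):
        if frame_line_color == "orange":
            return _orange_mask(pixels)
        if frame_line_color == "white":
            return _white_mask(pixels)
        raise ValueError(f"unknown frame line color {frame_line_color!r}")
    center, tol = frame_line_color
    return _custom_mask(pixels, center, tol)


def _side_thickness(cov: np.ndarray, threshold: float = 0.9) -> int:
    """Leading run length of coverage >= threshold (line thickness)."""
    below = np.nonzero(cov < threshold)[0]
    return int(below[0]) if below.size else len(cov)


def detect_elastogram_box(frame: FrameImage, frame_line_color="orange",
                          min_perimeter_frac: float = 0.9,
                          min_side_px: int = 16) -> tuple:
    """Find the interior rectangle of the colored frame line around the elastogram.

    Matching pixels are grouped into connected components; a component is a
    valid ring if >= ``min_perimeter_frac`` of its bounding-box perimeter is
    matched. The largest valid ring wins, and the measured line thickness on
    each side is excluded from the returned half-open interior rectangle.

    Raises
    ------
    SegmentationError
        If no valid ring is found — switch to manual segmentation.
    """
    pixels = frame.pixels
    mask = _line_mask(pixels, frame_line_color)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise SegmentationError(
            "no frame-line pixels found; segment the elastogram manually "
            "(provide a box and mm_per_px)")

    best = None  # (area, interior)
    for comp_id, slc in enumerate(ndimage.find_objects(labels), start=1):
        if slc is None:
            continue
        sub = labels[slc] == comp_id
        h, w = sub.shape
        if h < min_side_px or w < min_side_px:
            continue
        border = np.concatenate([sub[0, :], sub[-1, :], sub[1:-1, 0], sub[1:-1, -1]])
        if border.mean() < min_perimeter_frac:
            continue
        t_top = _side_thickness(sub.mean(axis=1))
        t_bot = _side_thickness(sub[::-1].mean(axis=1))
        t_left = _side_thickness(sub.mean(axis=0))
        t_right = _side_thickness(sub[:, ::-1].mean(axis=0))
        r0 = slc[0].start + t_top
        r1 = slc[0].stop - t_bot
        c0 = slc[1].start + t_left
        c1 = slc[1].stop - t_right
        if r1 <= r0 or c1 <= c0:
            continue
        area = h * w
        if best is None or area > best[0]:
            best = (area, (r0, r1, c0, c1))

    if best is None:
        raise SegmentationError(
            "no connected frame-line ring found; segment the elastogram "
            "manually (provide a box and mm_per_px)")
    return best[1]


def detect_scale(frame: FrameImage, ruler_region, tick_interval_mm: float = 10.0) -> float:
    """Calibrate mm per pixel from the measurement bar's tick marks.

    The brightness profile of the ruler region (averaged across its columns)
    is scanned for local maxima; the scale is ``tick_interval_mm`` divided by
    the median inter-tick spacing in pixels.

    Raises
    ------
    ScaleDetectionError
        If fewer than two ticks are found — supply mm_per_px manually.
    """
    if tick_interval_mm <= 0:
        raise ValueError("tick_interval_mm must be positive")
    r0, r1, c0, c1 = ruler_region
    H, W = frame.pixels.shape[:2]
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ScaleDetectionError(
            f"ruler region {ruler_region} lies outside the {H}x{W} frame; "
            "supply mm_per_px manually")
    profile = frame.pixels[r0:r1, c0:c1].astype(float).mean(axis=(1, 2))
    spread = profile.max() - profile.min()
    if spread <= 0:
        raise ScaleDetectionError(
            "ruler region is uniform (no tick marks); supply mm_per_px manually")
    peaks, _ = find_peaks(profile, prominence=0.5 * spread)
    if len(peaks) < 2:
        raise ScaleDetectionError(
            f"found {len(peaks)} tick mark(s) in the ruler region, need >= 2; "
            "supply mm_per_px manually")
    spacing = float(np.median(np.diff(peaks)))
    return tick_interval_mm / spacing


def manual_geometry(frame: FrameImage, box, mm_per_px: float) -> ElastogramGeometry:
    """Build geometry from a user-specified box and scale, validated against the frame."""
    H, W = frame.pixels.shape[:2]
    r0, r1, c0, c1 = (int(v) for v in box)
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"manual box {box} lies outside the {H}x{W} frame")
    return ElastogramGeometry(box=(r0, r1, c0, c1), mm_per_px=mm_per_px, mode="manual")


def auto_geometry(frames, reference_frame: int = 0, frame_line_color="orange",
                  ruler_region=None, tick_interval_mm: float = 10.0,
                  mm_per_px: float | None = None) -> ElastogramGeometry:
    """Detect geometry on one reference frame and reuse it for the whole clip.

    The box is detected from the frame line; the scale comes from
    ``mm_per_px`` if given, otherwise from the measurement bar in
    ``ruler_region``.
    """
    if not frames:
        raise ValueError("clip has no frames")
    if not (0 <= reference_frame < len(frames)):
        raise ValueError(f"reference frame {reference_frame} out of range "
                         f"for a {len(frames)}-frame clip")
    ref = frames[reference_frame]
    box = detect_elastogram_box(ref, frame_line_color)
    if mm_per_px is None:
        if ruler_region is None:
            raise ScaleDetectionError(
                "no ruler region configured and no manual mm_per_px given")
        mm_per_px = detect_scale(ref, ruler_region, tick_interval_mm)
    return ElastogramGeometry(box=box, mm_per_px=mm_per_px, mode="auto")
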