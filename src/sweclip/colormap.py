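"""Elasticity colormap modelling: forward rendering and inversion.

Shear-wave elastography systems overlay a color heatmap (the elastogram) on
the grayscale B-mode image at 50% opacity. Each overlay color encodes Young's
modulus linearly between 0 kPa (first stop, blue) and the user-set scale
maximum (last stop, red). This module models that mapping in both directions:
elasticity values to displayed RGB (including the alpha blend over the
unknown gray background), and observed RGB pixels back to kPa.

Inversion is a nearest-neighbour search over the finite set of *achievable*
blended colors ``{alpha * lut[k] + (1 - alpha) * g}`` for all LUT indices k
and a grid of background gray levels g, rather than an algebraic unblend: the
per-pixel background gray is unknown, so exact inversion is underdetermined,
while the nearest achievable blend is well-defined and enumerable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DEFAULT_STOPS",
    "ColormapSpec",
    "ElasticityScale",
    "PixelClass",
    "value_to_rgb",
    "blend_over_gray",
    "classify_pixel",
    "classify_pixels",
    "decode_pixel",
    "decode_pixels",
    "sample_colorbar",
    "round_half_away",
]

# Blue -> cyan -> green -> yellow -> orange -> red at uniform positions.
# The vendor's "temperature gradient" map is not published; this stands in for
# it and is replaced by color-bar sampling (sample_colorbar) or a user stop
# file whenever either is available.
DEFAULT_STOPS = (
    (0.0, (0, 0, 255)),
    (0.2, (0, 255, 255)),
    (0.4, (0, 255, 0)),
    (0.6, (255, 255, 0)),
    (0.8, (255, 128, 0)),
    (1.0, (255, 0, 0)),
)

DEFAULT_CHROMA_TOL = 8.0
DEFAULT_GAMUT_TOL = 12.0
DEFAULT_GRAY_STEP = 4

# label codes used by the vectorised classifier
LABEL_GRAYSCALE = 0
LABEL_COLORED = 1
LABEL_OUT_OF_GAMUT = 2


class PixelClass(Enum):
    """Classification of a single display pixel."""

    GRAYSCALE = "grayscale"
    COLORED = "colored"
    OUT_OF_GAMUT = "out_of_gamut"


_LABEL_TO_CLASS = {
    LABEL_GRAYSCALE: PixelClass.GRAYSCALE,
    LABEL_COLORED: PixelClass.COLORED,
    LABEL_OUT_OF_GAMUT: PixelClass.OUT_OF_GAMUT,
}


def round_half_away(x):
    """Round half away from zero (the fixture rendering convention)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ElasticityScale:
    """Maximum of the displayed elasticity color bar, in kPa (user input)."""

    e_max: float

    def __post_init__(self):
        if not np.isfinite(self.e_max) or self.e_max <= 0:
            raise ValueError(f"e_max must be a positive finite kPa value, got {self.e_max!r}")


@dataclass(frozen=True)
class ColormapSpec:
    """Ordered color stops mapping normalised elasticity to RGB.

    Parameters
    ----------
    stops
        Sequence of ``(position, (r, g, b))`` with positions strictly
        increasing from 0 to 1 and 8-bit channel values. The first stop is
        the lowest-elasticity color, the last the highest.
    n_lut
        Number of discrete samples of the piecewise-linear map used for
        decoding (>= 32). Decoded values are quantised to
        ``e_max * k / (n_lut - 1)``.
    alpha
        Opacity of the elastogram overlay, in (0, 1]; 0.5 is the device
        default the tool is designed for.
    """

    stops: tuple = DEFAULT_STOPS
    n_lut: int = 256
    alpha: float = 0.5

    def __post_init__(self):
        stops = tuple(
            (float(p), (int(c[0]), int(c[1]), int(c[2]))) for p, c in self.stops
        )
        object.__setattr__(self, "stops", stops)
        if len(stops) < 2:
            raise ValueError("a colormap needs at least 2 stops")
        pos = np.array([p for p, _ in stops])
        if pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValueError("stop positions must start at 0 and end at 1")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("stop positions must be strictly increasing")
        for _, c in stops:
            if any(ch < 0 or ch > 255 for ch in c):
                raise ValueError(f"channel values must be 8-bit, got {c}")
        if self.n_lut < 32:
            raise ValueError("n_lut must be >= 32")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.stops])

    @property
    def colors(self) -> np.ndarray:
        return np.array([c for _, c in self.stops], dtype=float)

    def interpolate(self, t) -> np.ndarray:
        """Piecewise-linear color at normalised position(s) ``t`` in [0, 1]."""
        t = np.asarray(t, dtype=float)
        pos, cols = self.positions, self.colors
        out = np.stack([np.interp(t, pos, cols[:, i]) for i in range(3)], axis=-1)
        return out

    def lut(self) -> np.ndarray:
        """The ``(n_lut, 3)`` discretised color table (float channels)."""
        return self.interpolate(np.linspace(0.0, 1.0, self.n_lut))

    def span(self) -> float:
        """Minimum peak-to-peak channel range over the LUT (8-bit units).

        Enters the round-trip error bound: one 8-bit rounding unit moves the
        decoded value by at most ``e_max / span``.
        """
        lut = self.lut()
        return float(np.min(lut.max(axis=0) - lut.min(axis=0)))

    @classmethod
    def from_csv(cls, path, n_lut: int = 256, alpha: float = 0.5) -> "ColormapSpec":
        """Load stops from a CSV file with header ``position,r,g,b``."""
        path = Path(path)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"position", "r", "g", "b"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV header position,r,g,b")
            stops = [
                (float(row["position"]), (int(row["r"]), int(row["g"]), int(row["b"])))
                for row in reader
            ]
        return cls(stops=tuple(stops), n_lut=n_lut, alpha=alpha)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["position", "r", "g", "b"])
            for p, (r, g, b) in self.stops:
                writer.writerow([p, r, g, b])


def value_to_rgb(v, scale: ElasticityScale, cmap: ColormapSpec = ColormapSpec()) -> np.ndarray:
    """Forward map: elasticity in kPa to the (real-valued) overlay color.

    ``v / e_max`` is clamped to [0, 1] before piecewise-linear interpolation
    between the enclosing stops. Accepts scalars or arrays (vectorised over
    leading dimensions; the result gains a trailing channel axis).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("elasticity values must be finite")
    if np.any(v < 0):
        raise ValueError("elasticity values must be >= 0")
    t = np.clip(v / scale.e_max, 0.0, 1.0)
    return cmap.interpolate(t)


def blend_over_gray(color, gray, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend overlay color(s) over a B-mode gray level.

    Each channel becomes ``alpha * color + (1 - alpha) * gray``. ``color`` is
    ``(..., 3)``, ``gray`` a scalar or ``(...)`` array of 8-bit levels.
    """
    color = np.asarray(color, dtype=float)
    gray = np.asarray(gray, dtype=float)
    if color.shape[-1] != 3:
        raise ValueError("color must have a trailing channel axis of size 3")
    if np.any(color < 0) or np.any(color > 255):
        raise ValueError("color channels must lie in [0, 255]")
    if np.any(gray < 0) or np.any(gray > 255):
        raise ValueError("gray level must lie in [0, 255]")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return alpha * color + (1.0 - alpha) * gray[..., np.newaxis]


@lru_cache(maxsize=8)
def _blended_index(cmap: ColormapSpec, gray_step: int):
    """All achievable blended colors, ordered by (LUT index, gray), + KD-tree."""
    lut = cmap.lut()
    grays = np.arange(0, 256, gray_step, dtype=float)
    if grays[-1] != 255.0:
        grays = np.append(grays, 255.0)
    blended = cmap.alpha * lut[:, np.newaxis, :] + (1.0 - cmap.alpha) * grays[np.newaxis, :, np.newaxis]
    flat = blended.reshape(-1, 3)
    lut_index = np.repeat(np.arange(cmap.n_lut), len(grays))
    # collapse duplicate achievable colors onto their lowest LUT index so
    # exact ties resolve deterministically toward the lower index
    _, first = np.unique(flat, axis=0, return_index=True)
    first.sort()
    flat, lut_index = flat[first], lut_index[first]
    return flat, lut_index, cKDTree(flat)


def _decode_core(px: np.ndarray, cmap: ColormapSpec, chroma_tol: float,
                 gamut_tol: float, gray_step: int):
    """Classify flat ``(n, 3)`` pixels and find best LUT index for each.

    Returns ``(labels, k_best)`` where ``k_best`` is -1 for grayscale pixels
    and the nearest-achievable LUT index otherwise (ties broken toward the
    lower index).
    """
    chroma = px.max(axis=1) - px.min(axis=1)
    grayscale = chroma <= chroma_tol
    labels = np.full(len(px), LABEL_GRAYSCALE, dtype=np.int8)
    k_best = np.full(len(px), -1, dtype=np.int64)

    query = ~grayscale
    if np.any(query):
        flat, lut_index, tree = _blended_index(cmap, gray_step)
        k_nn = min(8, len(flat))
        dists, nbrs = tree.query(px[query], k=k_nn)
        if k_nn == 1:
            dists = dists[:, np.newaxis]
            nbrs = nbrs[:, np.newaxis]
        dmin = dists[:, 0]
        # resolve exact distance ties toward the lower LUT index
        tied = dists <= dmin[:, np.newaxis] + 1e-9
        cand_k = np.where(tied, lut_index[nbrs], cmap.n_lut + 1)
        k_best[query] = cand_k.min(axis=1)
        labels[query] = np.where(dmin <= gamut_tol, LABEL_COLORED, LABEL_OUT_OF_GAMUT)
    return labels, k_best


def classify_pixels(pixels, cmap: ColormapSpec = ColormapSpec(),
                    chroma_tol: float = DEFAULT_CHROMA_TOL,
                    gamut_tol: float = DEFAULT_GAMUT_TOL,
                    gray_step: int = DEFAULT_GRAY_STEP) -> np.ndarray:
    """Vectorised pixel classification.

    Returns an integer label array (same leading shape as ``pixels``):
    0 = grayscale, 1 = colored, 2 = out of gamut. A pixel is grayscale iff
    its channel range is <= ``chroma_tol``; otherwise colored iff its distance
    to the nearest achievable blended colormap color is <= ``gamut_tol``.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[-1] != 3:
        raise ValueError("pixels must have a trailing channel axis of size 3")
    shape = pixels.shape[:-1]
    labels, _ = _decode_core(pixels.reshape(-1, 3), cmap, chroma_tol, gamut_tol, gray_step)
    return labels.reshape(shape)


def classify_pixel(p, cmap: ColormapSpec = ColormapSpec(),
                   chroma_tol: float = DEFAULT_CHROMA_TOL,
                   gamut_tol: float = DEFAULT_GAMUT_TOL,
                   gray_step: int = DEFAULT_GRAY_STEP) -> PixelClass:
    """Classify one RGB pixel as grayscale, colored, or out of gamut."""
    label = classify_pixels(np.asarray(p, dtype=float)[np.newaxis, :],
                            cmap, chroma_tol, gamut_tol, gray_step)[0]
    return _LABEL_TO_CLASS[int(label)]


def decode_pixels(pixels, scale: ElasticityScale, cmap: ColormapSpec = ColormapSpec(),
                  chroma_tol: float = DEFAULT_CHROMA_TOL,
                  gamut_tol: float = DEFAULT_GAMUT_TOL,
                  gray_step: int = DEFAULT_GRAY_STEP,
                  out_of_gamut: str = "absent"):
    """Vectorised decode of observed pixels back to kPa.

    Returns ``(values, labels)``: ``values`` holds
    ``e_max * k / (n_lut - 1)`` for decoded pixels and NaN where the pixel
    carries no elasticity value. Grayscale pixels never decode; out-of-gamut
    pixels decode only with ``out_of_gamut="nearest"``.
    """
    if out_of_gamut not in ("absent", "nearest"):
        raise ValueError('out_of_gamut must be "absent" or "nearest"')
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[-1] != 3:
        raise ValueError("pixels must have a trailing channel axis of size 3")
    shape = pixels.shape[:-1]
    labels, k_best = _decode_core(pixels.reshape(-1, 3), cmap, chroma_tol, gamut_tol, gray_step)
    decoded = labels == LABEL_COLORED
    if out_of_gamut == "nearest":
        decoded |= labels == LABEL_OUT_OF_GAMUT
    values = np.full(len(labels), np.nan)
    values[decoded] = scale.e_max * k_best[decoded] / (cmap.n_lut - 1)
    return values.reshape(shape), labels.reshape(shape)


def decode_pixel(p, scale: ElasticityScale, cmap: ColormapSpec = ColormapSpec(),
                 chroma_tol: float = DEFAULT_CHROMA_TOL,
                 gamut_tol: float = DEFAULT_GAMUT_TOL,
                 gray_step: int = DEFAULT_GRAY_STEP,
                 out_of_gamut: str = "absent"):
    """Decode one pixel to kPa, or ``None`` if it carries no elasticity value."""
    values, _ = decode_pixels(np.asarray(p, dtype=float)[np.newaxis, :], scale, cmap,
                              chroma_tol, gamut_tol, gray_step, out_of_gamut)
    v = float(values[0])
    return None if np.isnan(v) else v


def roundtrip_tolerance(scale: ElasticityScale, cmap: ColormapSpec) -> float:
    """Worst-case decode error bound for forward-rendered, rounded pixels.

    LUT quantisation contributes ``e_max / (n_lut - 1)``; channel rounding
    (+-1 per channel, doubled through the 50% blend) contributes
    ``2 * e_max / span`` where ``span`` is the minimum channel range.
    """
    return scale.e_max / (cmap.n_lut - 1) + scale.e_max * 2.0 / cmap.span()


def sample_colorbar(frame, bar_box, scale: ElasticityScale | None = None,
                    n_stops: int = 6, top_is_max: bool = True,
                    n_lut: int = 256, alpha: float = 0.5) -> ColormapSpec:
    """Recover the colormap by sampling the displayed color bar.

    The displayed bar is the only in-image source of the device's true
    colormap. ``n_stops`` evenly spaced rows of the bar region are sampled
    (median color across each row) and become stops at uniform positions in
    [0, 1]. By default the top row maps to the scale maximum.

    Parameters
    ----------
    frame
        ``FrameImage`` or an ``(H, W, 3)`` array.
    bar_box
        ``(row_start, row_stop, col_start, col_stop)`` half-open pixel
        rectangle of the bar within the frame.
    """
    pixels = getattr(frame, "pixels", frame)
    pixels = np.asarray(pixels)
    r0, r1, c0, c1 = bar_box
    H, W = pixels.shape[:2]
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"bar_box {bar_box} lies outside the {H}x{W} frame")
    if n_stops < 2:
        raise ValueError("need at least 2 samples of the color bar")
    bar = pixels[r0:r1, c0:c1].astype(float)
    row_medians = np.median(bar, axis=1)  # (H_bar, 3)
    # sample at fractional rows so the stops line up with uniform positions
    # even when the bar height is not a multiple of n_stops - 1
    targets = np.linspace(0, bar.shape[0] - 1, n_stops)
    rows = np.arange(bar.shape[0])
    sampled = np.stack([np.interp(targets, rows, row_medians[:, ch])
                        for ch in range(3)], axis=-1)  # top to bottom
    if top_is_max:
        sampled = sampled[::-1]  # position 0 = lowest elasticity = bottom row
    colors = [tuple(int(round(ch)) for ch in c) for c in sampled]
    if len(set(colors)) < 2:
        raise ValueError("color bar region is uniform; cannot recover a colormap")
    positions = np.linspace(0.0, 1.0, n_stops)
    stops = tuple((float(p), c) for p, c in zip(positions, colors))
    return ColormapSpec(stops=stops, n_lut=n_lut, alpha=alpha)
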