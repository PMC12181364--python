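"""Per-frame elastogram decoding and the clip-level statistic vector.

Each displayed frame is decoded individually (no temporal averaging) into an
elasticity field over the elastogram box. For every frame the ROI yields the
statistic vector: the fill percentage (fraction of ROI pixels that carry an
elasticity color — the image-quality proxy), mean, median, standard
deviation (n-1 denominator), interquartile range (linear-interpolation
quantiles), maximum, and the count/percentage of values exceeding 98% of the
scale maximum. Clip summaries are arithmetic means over frames that contain
at least one valid pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colormap import ColormapSpec, ElasticityScale, decode_pixels
from .roi import RoiMask
from .segmentation import ElastogramGeometry, FrameImage
from .units import DEFAULT_TISSUE, TissueConstants, young_to_swv

__all__ = [
    "ElasticityField",
    "FrameStats",
    "ClipSummary",
    "ClipAnalysis",
    "decode_frame",
    "frame_stats",
    "frame_stats_by_cell",
    "summarize_clip",
    "analyze_clip",
    "FRAME_TABLE_COLUMNS",
]

DEFAULT_TOP_FRACTION = 0.02

FRAME_TABLE_COLUMNS = [
    "frame_index", "cell_id", "n_roi_px", "n_valid", "fill_pct",
    "mean_kpa", "median_kpa", "sd_kpa", "iqr_kpa", "max_kpa",
    "n_top", "pct_top",
]


@dataclass
class ElasticityField:
    """Decoded per-pixel elasticity (kPa) over the elastogram box.

    ``values`` is NaN wherever ``valid`` is False; valid pixels are exactly
    those classified as colored.
    """

    values: np.ndarray
    valid: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("valid pixels must hold finite values")


@dataclass
class FrameStats:
    """The per-frame statistic vector over one ROI (or one grid cell)."""

    frame_index: int
    n_roi_px: int
    n_valid: int
    fill_pct: float
    mean: float | None
    median: float | None
    sd: float | None
    iqr: float | None
    max: float | None
    n_top: int | None
    pct_top: float | None
    cell_id: int = 0  # 0 = pooled ROI, >= 1 = grid cell

    def to_row(self) -> dict:
        return {
            "frame_index": self.frame_index, "cell_id": self.cell_id,
            "n_roi_px": self.n_roi_px, "n_valid": self.n_valid,
            "fill_pct": self.fill_pct, "mean_kpa": self.mean,
            "median_kpa": self.median, "sd_kpa": self.sd,
            "iqr_kpa": self.iqr, "max_kpa": self.max,
            "n_top": self.n_top, "pct_top": self.pct_top,
        }


@dataclass
class ClipSummary:
    """Across-frame arithmetic means of the per-frame statistics.

    Frames with no valid pixel carry no stiffness information and are
    excluded (``n_frames_used`` counts the rest). Optional SWV conversions
    of the location statistics are attached when requested.
    """

    n_frames_total: int
    n_frames_used: int
    fill_pct: float | None = None
    mean: float | None = None
    median: float | None = None
    sd: float | None = None
    iqr: float | None = None
    max: float | None = None
    n_top: float | None = None
    pct_top: float | None = None
    mean_swv: float | None = None
    median_swv: float | None = None
    max_swv: float | None = None

    def to_row(self) -> dict:
        return {
            "n_frames_total": self.n_frames_total,
            "n_frames_used": self.n_frames_used,
            "fill_pct": self.fill_pct, "mean_kpa": self.mean,
            "median_kpa": self.median, "sd_kpa": self.sd,
            "iqr_kpa": self.iqr, "max_kpa": self.max,
            "n_top": self.n_top, "pct_top": self.pct_top,
            "mean_swv_ms": self.mean_swv, "median_swv_ms": self.median_swv,
            "max_swv_ms": self.max_swv,
        }


@dataclass
class ClipAnalysis:
    """End-to-end result of analysing one clip."""

    frames_table: pd.DataFrame
    summary: ClipSummary
    errors: list = field(default_factory=list)  # (frame_index, message)


def decode_frame(frame: FrameImage, geom: ElastogramGeometry,
                 cmap: ColormapSpec = ColormapSpec(),
                 scale: ElasticityScale = None,
                 **decode_options) -> ElasticityField:
    """Decode the elastogram box of one frame to an elasticity field."""
    if scale is None:
        raise ValueError("an ElasticityScale (the color-bar maximum) is required")
    H, W = frame.pixels.shape[:2]
    r0, r1, c0, c1 = geom.box
    if r1 > H or c1 > W:
        raise ValueError(f"geometry box {geom.box} exceeds the {H}x{W} frame")
    crop = frame.pixels[r0:r1, c0:c1]
    values, labels = decode_pixels(crop, scale, cmap, **decode_options)
    valid = ~np.isnan(values)
    return ElasticityField(values=values, valid=valid, frame_index=frame.index)


def _stats_from_values(vals: np.ndarray, n_roi_px: int, frame_index: int,
                       e_max: float, top_fraction: float,
                       pct_top_of_total: bool, cell_id: int) -> FrameStats:
    n_valid = int(vals.size)
    fill_pct = 100.0 * n_valid / n_roi_px if n_roi_px else 0.0
    if n_valid == 0:
        return FrameStats(frame_index, n_roi_px, 0, fill_pct,
                          None, None, None, None, None, None, None, cell_id)
    q25, q75 = np.percentile(vals, [25, 75])
    threshold = (1.0 - top_fraction) * e_max
    n_top = int(np.sum(vals > threshold))
    denom = n_roi_px if pct_top_of_total else n_valid
    return FrameStats(
        frame_index=frame_index, n_roi_px=n_roi_px, n_valid=n_valid,
        fill_pct=fill_pct,
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        sd=float(vals.std(ddof=1)) if n_valid >= 2 else None,
        iqr=float(q75 - q25),
        max=float(vals.max()),
        n_top=n_top,
        pct_top=100.0 * n_top / denom if denom else None,
        cell_id=cell_id,
    )


def frame_stats(field: ElasticityField, roi: RoiMask, scale: ElasticityScale,
                top_fraction: float = DEFAULT_TOP_FRACTION,
                pct_top_of_total: bool = False, cell_id: int = 0) -> FrameStats:
    """Statistic vector over valid values inside the ROI mask.

    ``n_top`` counts values exceeding ``(1 - top_fraction) * e_max`` (i.e.
    the top 2% of the scale maximum by default); ``pct_top`` is relative to
    the valid pixels unless ``pct_top_of_total``.
    """
    if roi.mask.shape != field.values.shape:
        raise ValueError("ROI mask shape does not match the elasticity field")
    vals = field.values[roi.mask & field.valid]
    return _stats_from_values(vals, int(roi.mask.sum()), field.frame_index,
                              scale.e_max, top_fraction, pct_top_of_total, cell_id)


def frame_stats_by_cell(field: ElasticityField, roi: RoiMask, scale: ElasticityScale,
                        top_fraction: float = DEFAULT_TOP_FRACTION,
                        pct_top_of_total: bool = False) -> list:
    """Per-grid-cell statistic vectors (cells labelled 1..n_cells)."""
    out = []
    for cell in range(1, roi.n_cells + 1):
        cell_mask = roi.cell_id == cell
        vals = field.values[cell_mask & field.valid]
        out.append(_stats_from_values(vals, int(cell_mask.sum()), field.frame_index,
                                      scale.e_max, top_fraction, pct_top_of_total, cell))
    return out


def _mean_or_none(values) -> float | None:
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        return None
    return float(np.nanmean(arr))


def summarize_clip(stats: list, units: str = "kpa",
                   const: TissueConstants = DEFAULT_TISSUE) -> ClipSummary:
    """Across-frame means of the per-frame statistics (pooled-ROI rows)."""
    if len(stats) == 0:
        raise ValueError("cannot summarise an empty list of frame statistics")
    used = [s for s in stats if s.n_valid > 0]
    summary = ClipSummary(n_frames_total=len(stats), n_frames_used=len(used))
    if used:
        summary.fill_pct = _mean_or_none([s.fill_pct for s in used])
        summary.mean = _mean_or_none([s.mean for s in used])
        summary.median = _mean_or_none([s.median for s in used])
        summary.sd = _mean_or_none([s.sd for s in used])
        summary.iqr = _mean_or_none([s.iqr for s in used])
        summary.max = _mean_or_none([s.max for s in used])
        summary.n_top = _mean_or_none([s.n_top for s in used])
        summary.pct_top = _mean_or_none([s.pct_top for s in used])
        if units in ("swv", "both"):
            for src, dst in (("mean", "mean_swv"), ("median", "median_swv"),
                             ("max", "max_swv")):
                v = getattr(summary, src)
                if v is not None:
                    setattr(summary, dst, young_to_swv(v, const))
    return summary


def analyze_clip(frames, geom: ElastogramGeometry, roi: RoiMask,
                 cmap: ColormapSpec = ColormapSpec(),
                 scale: ElasticityScale = None,
                 units: str = "kpa",
                 const: TissueConstants = DEFAULT_TISSUE,
                 top_fraction: float = DEFAULT_TOP_FRACTION,
                 pct_top_of_total: bool = False,
                 decode_options: dict | None = None) -> ClipAnalysis:
    """Decode every frame and assemble the per-frame table and clip summary.

    Frames that fail to process are recorded in ``errors`` without aborting
    the rest of the clip. In grid mode the table holds one row per cell per
    frame plus a pooled row (``cell_id`` 0) per frame; the summary averages
    the pooled rows.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("clip has no frames")
    if units not in ("kpa", "swv", "both"):
        raise ValueError("units must be 'kpa', 'swv' or 'both'")
    decode_options = decode_options or {}

    rows, pooled, errors = [], [], []
    for frame in frames:
        try:
            field = decode_frame(frame, geom, cmap, scale, **decode_options)
            if roi.n_cells > 0:
                for s in frame_stats_by_cell(field, roi, scale, top_fraction,
                                             pct_top_of_total):
                    rows.append(s.to_row())
            s = frame_stats(field, roi, scale, top_fraction, pct_top_of_total)
            pooled.append(s)
            rows.append(s.to_row())
        except Exception as exc:  # keep processing the remaining frames
            errors.append((frame.index, str(exc)))

    if not pooled:
        raise RuntimeError(f"no frame could be analysed: {errors}")
    table = pd.DataFrame(rows, columns=FRAME_TABLE_COLUMNS)
    if units in ("swv", "both"):
        for col in ("mean_kpa", "median_kpa", "max_kpa"):
            table[col.replace("_kpa", "_swv_ms")] = young_to_swv(
                table[col].to_numpy(dtype=float), const)
        if units == "swv":
            table = table.drop(columns=["mean_kpa", "median_kpa", "max_kpa"])
    summary = summarize_clip(pooled, units=units, const=const)
    return ClipAnalysis(frames_table=table, summary=summary, errors=errors)
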