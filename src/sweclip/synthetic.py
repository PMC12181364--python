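"""Render ground-truth SWE clips so every pipeline stage is testable.

The renderer emulates the exported clip layout the analyzer expects: a
gray-noise B-mode background, the elastogram alpha-blended over it inside a
box, a colored frame line around the box, a measurement bar with tick marks,
and a solid color bar. The underlying elasticity field is known exactly, so
decoding, segmentation, scale calibration and the statistics can all be
checked against ground truth. Rendering is bit-reproducible given the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .colormap import ColormapSpec, ElasticityScale, blend_over_gray, round_half_away, value_to_rgb
from .clipstats import ElasticityField
from .segmentation import FrameImage

__all__ = ["SyntheticClipConfig", "generate_field", "render_frame", "render_clip",
           "clip_ground_truth", "write_clip"]

FIELD_MODELS = ("constant", "gradient", "smooth-random")

# sub-stream tags so spatial structure, jitter, dropout and background draw
# from independent, frame-addressable streams of the one configured seed
_TAG_SPATIAL, _TAG_JITTER, _TAG_DROPOUT, _TAG_BACKGROUND = 11, 23, 37, 53


@dataclass
class SyntheticClipConfig:
    """Layout and field model of a rendered clip.

    The elastogram box, ruler and color bar are half-open pixel rectangles
    within the ``height x width`` frame. ``amplitude_kpa`` is the full ramp
    range for the gradient model and the spatial standard deviation for the
    smooth-random model; fields are clipped to ``[0, e_max]``.
    """

    height: int = 360
    width: int = 480
    box: tuple = (60, 260, 100, 420)
    mm_per_px: float = 0.1
    e_max: float = 300.0
    field_model: str = "smooth-random"
    base_kpa: float = 120.0
    amplitude_kpa: float = 60.0
    corr_length_px: float = 15.0
    temporal_jitter_sd_kpa: float = 5.0
    dropout_fraction: float = 0.0
    background_mean: float = 60.0
    background_sd: float = 25.0
    cmap: ColormapSpec = dc_field(default_factory=ColormapSpec)
    frame_line: str | tuple = "orange"
    frame_line_width: int = 1
    ruler_region: tuple = (60, 340, 20, 40)
    tick_interval_mm: float = 10.0
    colorbar_region: tuple = (60, 261, 448, 470)
    n_frames: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.field_model not in FIELD_MODELS:
            raise ValueError(f"field_model must be one of {FIELD_MODELS}")
        r0, r1, c0, c1 = self.box
        w = self.frame_line_width
        if w < 1:
            raise ValueError("frame_line_width must be >= 1")
        if not (w <= r0 < r1 <= self.height - w and w <= c0 < c1 <= self.width - w):
            raise ValueError("elastogram box (plus frame line) must fit inside the frame")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.e_max <= 0 or self.mm_per_px <= 0:
            raise ValueError("e_max and mm_per_px must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def scale(self) -> ElasticityScale:
        return ElasticityScale(self.e_max)

    @property
    def line_color(self) -> tuple:
        if self.frame_line == "orange":
            return (255, 128, 0)
        if self.frame_line == "white":
            return (255, 255, 255)
        return tuple(int(v) for v in self.frame_line)

    def variant(self, **changes) -> "SyntheticClipConfig":
        return replace(self, **changes)


def _spatial_base(config: SyntheticClipConfig) -> np.ndarray:
    """Frame-independent spatial component of the field."""
    r0, r1, c0, c1 = config.box
    H, W = r1 - r0, c1 - c0
    if config.field_model == "constant":
        return np.full((H, W), config.base_kpa)
    if config.field_model == "gradient":
        ramp = np.linspace(0.0, config.amplitude_kpa, W)
        return config.base_kpa + np.broadcast_to(ramp, (H, W)).copy()
    rng = np.random.default_rng([config.seed, _TAG_SPATIAL])
    noise = rng.standard_normal((H, W))
    smooth = gaussian_filter(noise, sigma=config.corr_length_px)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return config.base_kpa + config.amplitude_kpa * smooth


def generate_field(config: SyntheticClipConfig, frame_index: int) -> ElasticityField:
    """Ground-truth elasticity field for one frame, deterministic in (seed, frame)."""
    values = _spatial_base(config).copy()
    if config.temporal_jitter_sd_kpa > 0:
        rng = np.random.default_rng([config.seed, _TAG_JITTER, frame_index])
        values = values + rng.normal(0.0, config.temporal_jitter_sd_kpa)
    values = np.clip(values, 0.0, config.e_max)
    valid = np.ones(values.shape, dtype=bool)
    if config.dropout_fraction > 0:
        rng = np.random.default_rng([config.seed, _TAG_DROPOUT, frame_index])
        valid = rng.random(values.shape) >= config.dropout_fraction
    out = np.where(valid, values, np.nan)
    return ElasticityField(values=out, valid=valid, frame_index=frame_index)


def render_frame(field: ElasticityField, config: SyntheticClipConfig) -> FrameImage:
    """Forward model of the display: blend, frame line, ruler, color bar."""
    rng = np.random.default_rng([config.seed, _TAG_BACKGROUND, field.frame_index])
    gray = np.clip(rng.normal(config.background_mean, config.background_sd,
                              (config.height, config.width)), 0, 255)
    gray = round_half_away(gray)
    canvas = np.repeat(gray[:, :, np.newaxis], 3, axis=2)

    r0, r1, c0, c1 = config.box
    w = config.frame_line_width
    canvas[r0 - w:r1 + w, c0 - w:c1 + w] = config.line_color

    # elastogram: blended where valid, bare background where dropped out
    box_gray = gray[r0:r1, c0:c1]
    overlay = np.repeat(box_gray[:, :, np.newaxis], 3, axis=2)
    if field.valid.any():
        colors = value_to_rgb(np.where(field.valid, field.values, 0.0),
                              config.scale, config.cmap)
        blended = round_half_away(
            blend_over_gray(colors, box_gray, config.cmap.alpha))
        overlay = np.where(field.valid[:, :, np.newaxis], blended, overlay)
    canvas[r0:r1, c0:c1] = overlay

    # measurement bar: dark band with bright ticks every tick_interval_mm
    rr0, rr1, rc0, rc1 = config.ruler_region
    canvas[rr0:rr1, rc0:rc1] = 20
    tick_px = int(round(config.tick_interval_mm / config.mm_per_px))
    for r in range(rr0 + 10, rr1, tick_px):
        canvas[r, rc0:rc1] = 230

    # color bar: solid, top row = e_max
    br0, br1, bc0, bc1 = config.colorbar_region
    hb = br1 - br0
    positions = 1.0 - np.arange(hb) / (hb - 1)
    bar = round_half_away(config.cmap.interpolate(positions))
    canvas[br0:br1, bc0:bc1] = bar[:, np.newaxis, :]

    return FrameImage(pixels=canvas.astype(np.uint8), index=field.frame_index)


def render_clip(config: SyntheticClipConfig):
    """All frames of the configured clip plus their ground-truth fields."""
    fields = [generate_field(config, i) for i in range(config.n_frames)]
    frames = [render_frame(f, config) for f in fields]
    return frames, fields


def clip_ground_truth(fields) -> pd.DataFrame:
    """Per-frame true statistics of the generating field (over the full box)."""
    rows = []
    for f in fields:
        vals = f.values[f.valid]
        rows.append({
            "frame_index": f.frame_index,
            "n_box_px": f.values.size,
            "n_valid_px": int(f.valid.sum()),
            "true_fill_pct": 100.0 * f.valid.mean(),
            "true_mean_kpa": float(vals.mean()) if vals.size else np.nan,
            "true_median_kpa": float(np.median(vals)) if vals.size else np.nan,
            "true_max_kpa": float(vals.max()) if vals.size else np.nan,
        })
    return pd.DataFrame(rows)


def write_clip(frames, fmt: str, path, truth: pd.DataFrame | None = None) -> dict:
    """Write a rendered clip through the real writers, plus the truth table.

    ``fmt`` is ``"png-stack"`` (a directory of zero-padded PNGs) or
    ``"dicom-multiframe"`` (one uncompressed RGB multi-frame file). Returns
    the written paths. Both encodings round-trip pixels losslessly.
    """
    from pathlib import Path
    import imageio.v3 as iio

    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("cannot write a clip with no frames")
    path = Path(path)
    written = {}
    if fmt == "png-stack":
        path.mkdir(parents=True, exist_ok=True)
        for frame in frames:
            p = path / f"frame_{frame.index:04d}.png"
            iio.imwrite(p, frame.pixels)
        written["clip"] = path
        truth_path = path / "ground_truth.csv"
    elif fmt == "dicom-multiframe":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_dicom(frames, path)
        written["clip"] = path
        truth_path = path.with_name(path.stem + "_ground_truth.csv")
    else:
        raise ValueError('format must be "png-stack" or "dicom-multiframe"')
    if truth is not None:
        truth.to_csv(truth_path, index=False)
        written["truth"] = truth_path
    return written


def _write_dicom(frames, path) -> None:
    """Uncompressed RGB multi-frame DICOM (deterministic UIDs)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    arr = np.stack([f.pixels for f in frames])
    n, H, W, _ = arr.shape
    entropy = f"sweclip-synthetic-{n}-{H}-{W}-{arr[:2].tobytes().hex()[:64]}"
    sop_uid = generate_uid(entropy_srcs=[entropy, "sop"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.7.4")
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy, "study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[entropy, "series"])
    ds.Modality = "US"
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SWECLIP-SYN"
    ds.Rows, ds.Columns = H, W
    ds.NumberOfFrames = n
    ds.SamplesPerPixel = 3
    ds.PhotometricInterpretation = "RGB"
    ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    payload = arr.tobytes()
    if len(payload) % 2:
        payload += b"\x00"
    ds.PixelData = payload
    ds.save_as(path, enforce_file_format=True)
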