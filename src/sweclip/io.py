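"""Clip readers, result writers, and the configuration-driven pipeline runner.

Input clips are multi-frame RGB DICOM files (the device's export format) or
a directory of zero-padded PNG frames (the fixture dialect). Outputs are CSV
spreadsheets — one per-frame table and one clip summary — plus a JSON/CSV
agreement report for method comparisons. Outputs are deterministic for a
given configuration and input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (PairedSeries, bland_altman_plot, compare_methods,
                        correlation_plot)
from .clipstats import ClipAnalysis, analyze_clip
from .colormap import ColormapSpec, ElasticityScale, sample_colorbar
from .roi import build_grid, build_rect_mask
from .segmentation import (ElastogramGeometry, FrameImage, auto_geometry,
                           manual_geometry)
from .units import TissueConstants

__all__ = ["ClipReadError", "RunConfig", "read_clip", "read_clips",
           "run_analyze", "run_compare"]

logger = logging.getLogger("sweclip")

FRAMES_CSV_HEADER = (
    "# sweclip per-frame statistics\n"
    "# units: *_kpa columns in kilopascal (Young's modulus); *_swv_ms columns in m/s;\n"
    "#        fill_pct and pct_top in percent\n"
    "# cell_id: 0 = pooled ROI row, >= 1 = grid cell (row-major)\n"
)
SUMMARY_CSV_HEADER = (
    "# sweclip clip summary (means over frames with at least one valid pixel)\n"
    "# units: *_kpa in kilopascal; *_swv_ms in m/s; fill_pct and pct_top in percent\n"
)


class ClipReadError(RuntimeError):
    """A clip file could not be read; the message names the file."""


def _to_rgb_uint8(arr: np.ndarray, origin) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, np.newaxis], 3, axis=2)
    if arr.ndim != 3:
        raise ClipReadError(f"{origin}: expected a 2-d or 3-d frame, got shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ClipReadError(f"{origin}: expected 3 channels, got {arr.shape[2]}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def read_clip(path, format_hint: str | None = None) -> list:
    """Read a clip into temporally ordered RGB frames.

    A directory is read as a PNG stack in lexical file order; a file is read
    as multi-frame DICOM. ``format_hint`` (``"png-stack"`` or ``"dicom"``)
    overrides the autodetection.
    """
    path = Path(path)
    if not path.exists():
        raise ClipReadError(f"{path}: no such file or directory")
    fmt = format_hint
    if fmt is None:
        fmt = "png-stack" if path.is_dir() else "dicom"

    if fmt == "png-stack":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise ClipReadError(f"{path}: directory contains no PNG frames")
        import imageio.v3 as iio
        frames = []
        for i, p in enumerate(files):
            try:
                arr = iio.imread(p)
            except Exception as exc:
                raise ClipReadError(f"{p}: unreadable PNG frame ({exc})") from exc
            frames.append(FrameImage(pixels=_to_rgb_uint8(arr, p), index=i))
        return frames

    if fmt == "dicom":
        import pydicom
        try:
            ds = pydicom.dcmread(path)
            arr = ds.pixel_array
        except Exception as exc:
            raise ClipReadError(f"{path}: unreadable DICOM file ({exc})") from exc
        if arr.ndim == 3:  # single RGB frame
            arr = arr[np.newaxis]
        if arr.ndim != 4:
            raise ClipReadError(f"{path}: unexpected DICOM pixel shape {arr.shape}")
        return [FrameImage(pixels=_to_rgb_uint8(arr[i], path), index=i)
                for i in range(arr.shape[0])]

    raise ValueError(f"unknown format hint {format_hint!r}")


def read_clips(paths, format_hint: str | None = None):
    """Batch reader: unreadable clips are reported, the rest are returned."""
    clips, failures = {}, []
    for p in paths:
        try:
            clips[Path(p)] = read_clip(p, format_hint)
        except ClipReadError as exc:
            logger.error("skipping clip: %s", exc)
            failures.append((Path(p), str(exc)))
    return clips, failures


@dataclass
class RunConfig:
    """Everything one analysis run needs; mirrors the CLI flags.

    Exactly one ROI mode must be set (``roi_rect_mm`` or ``grid``); manual
    segmentation requires both ``manual_box`` and ``mm_per_px``.
    """

    input: str = ""
    e_max: float = 0.0
    format: str | None = None
    colormap: str = "default"  # "default" | "colorbar" | path to a stop CSV
    colorbar_region: tuple | None = None
    frame_line: str = "orange"
    manual_box: tuple | None = None
    mm_per_px: float | None = None
    ruler_region: tuple | None = None
    tick_interval_mm: float = 10.0
    roi_rect_mm: tuple | None = None
    grid: bool = False
    cell_mm: float = 4.0
    reference_frame: int = 0
    units: str = "kpa"
    rho: float = 1000.0
    out_dir: str = "."
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.e_max <= 0:
            raise ValueError("e_max (the elasticity color-bar maximum, kPa) is required")
        if (self.roi_rect_mm is not None) == self.grid:
            raise ValueError("choose exactly one ROI mode: --roi X0,Y0,W,H or --grid")
        if self.manual_box is not None and self.mm_per_px is None:
            raise ValueError("manual segmentation requires both manual_box and mm_per_px")
        if self.colormap == "colorbar" and self.colorbar_region is None:
            raise ValueError("colormap='colorbar' requires colorbar_region")
        if self.units not in ("kpa", "swv", "both"):
            raise ValueError("units must be kpa, swv or both")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("colorbar_region", "manual_box", "ruler_region", "roi_rect_mm"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _resolve_geometry(frames, config: RunConfig) -> ElastogramGeometry:
    if config.manual_box is not None:
        return manual_geometry(frames[config.reference_frame],
                               config.manual_box, config.mm_per_px)
    return auto_geometry(frames, reference_frame=config.reference_frame,
                         frame_line_color=config.frame_line,
                         ruler_region=config.ruler_region,
                         tick_interval_mm=config.tick_interval_mm,
                         mm_per_px=config.mm_per_px)


def _resolve_colormap(frames, config: RunConfig) -> ColormapSpec:
    if config.colormap == "default":
        return ColormapSpec()
    if config.colormap == "colorbar":
        return sample_colorbar(frames[config.reference_frame],
                               config.colorbar_region)
    return ColormapSpec.from_csv(config.colormap)


@dataclass
class RunResult:
    paths: dict
    analysis: ClipAnalysis
    geometry: ElastogramGeometry


def run_analyze(config: RunConfig) -> RunResult:
    """Run the full pipeline for one clip and write its CSV outputs."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    frames = read_clip(config.input, config.format)
    logger.info("read %d frame(s) from %s", len(frames), config.input)

    geom = _resolve_geometry(frames, config)
    logger.info("geometry: box=%s mm_per_px=%.4f mode=%s", geom.box,
                geom.mm_per_px, geom.mode)
    cmap = _resolve_colormap(frames, config)
    scale = ElasticityScale(config.e_max)
    if config.grid:
        roi = build_grid(geom, config.cell_mm)
        logger.info("grid ROI: %d cells of %.3g mm", roi.n_cells, config.cell_mm)
    else:
        roi = build_rect_mask(geom, config.roi_rect_mm)
        logger.info("rectangle ROI: %s mm, %d px", config.roi_rect_mm,
                    int(roi.mask.sum()))

    analysis = analyze_clip(frames, geom, roi, cmap, scale, units=config.units,
                            const=TissueConstants(rho=config.rho))
    for idx, msg in analysis.errors:
        logger.warning("frame %d failed: %s", idx, msg)
    if analysis.summary.fill_pct is not None:
        logger.info("mean fill %.1f%% over %d/%d frames",
                    analysis.summary.fill_pct, analysis.summary.n_frames_used,
                    analysis.summary.n_frames_total)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = Path(config.input).stem or Path(config.input).name
    frames_path = out_dir / f"{stem}_frames.csv"
    summary_path = out_dir / f"{stem}_summary.csv"
    with open(frames_path, "w") as fh:
        fh.write(FRAMES_CSV_HEADER)
        analysis.frames_table.to_csv(fh, index=False)
    with open(summary_path, "w") as fh:
        fh.write(SUMMARY_CSV_HEADER)
        pd.DataFrame([analysis.summary.to_row()]).to_csv(fh, index=False)
    logger.info("wrote %s and %s", frames_path, summary_path)
    return RunResult(paths={"frames": frames_path, "summary": summary_path},
                     analysis=analysis, geometry=geom)


def run_compare(csv_a, csv_b, out_dir, id_col: str = "clip",
                value_col: str = "mean_kpa", unit: str = "kPa",
                delta=None, delta_log=None, plots: bool = True) -> dict:
    """Compare two per-clip summary CSVs and write the agreement report."""
    series = []
    for p in (csv_a, csv_b):
        df = pd.read_csv(p, comment="#")
        if df.empty:
            raise ValueError(f"{p}: no rows to compare")
        for col in (id_col, value_col):
            if col not in df.columns:
                raise ValueError(f"{p}: missing required column {col!r}")
        series.append(df.set_index(id_col)[value_col])
    report = compare_methods(series[0], series[1], unit=unit,
                             delta=delta, delta_log=delta_log)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"json": out_dir / "agreement_report.json",
             "csv": out_dir / "agreement_report.csv"}
    payload = report.to_dict()
    with open(paths["json"], "w") as fh:
        json.dump(payload, fh, indent=2)

    def flatten(prefix, obj, rows):
        if isinstance(obj, dict):
            for k, v in obj.items():
                flatten(f"{prefix}{k}." if prefix else f"{k}.", v, rows) \
                    if isinstance(v, dict) else rows.append(
                        {"statistic": f"{prefix}{k}", "value": v})
        return rows

    rows = flatten("", {k: v for k, v in payload.items() if k != "ids"}, [])
    pd.DataFrame(rows).to_csv(paths["csv"], index=False)

    if plots:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        common = series[0].index.intersection(series[1].index)
        paired = PairedSeries(series[0].loc[common].to_numpy(),
                              series[1].loc[common].to_numpy(), unit=unit)
        ax = bland_altman_plot(paired, result=report.bland_altman_raw)
        ax.figure.savefig(out_dir / "bland_altman_raw.png", dpi=120)
        plt.close(ax.figure)
        if report.bland_altman_log is not None:
            ax = bland_altman_plot(paired, result=report.bland_altman_log,
                                   log_transform=True)
            ax.figure.savefig(out_dir / "bland_altman_log.png", dpi=120)
            plt.close(ax.figure)
        ax = correlation_plot(paired)
        ax.figure.savefig(out_dir / "correlation.png", dpi=120)
        plt.close(ax.figure)
        paths["plots"] = out_dir
    return {"report": report, "paths": paths}
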