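"""Analysis masks inside the elastogram: a hand-drawn rectangle or a grid of squares.

The grid tiles the elastogram with equal squares (default 4 x 4 mm) anchored
at the box's top-left corner; partial boundary cells are excluded so every
cell covers the same area. Rectangles are given in millimetres relative to
the elastogram's top-left corner and rasterised with a pixel-centre
inclusion rule; all pixel rectangles are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import ElastogramGeometry

__all__ = ["RoiSpec", "RoiMask", "build_rect_mask", "build_grid"]

DEFAULT_CELL_MM = 4.0


@dataclass
class RoiSpec:
    """User-facing ROI request: either a rectangle (mm) or a grid of squares."""

    kind: str = "grid"
    rect_mm: tuple | None = None  # (x0, y0, width, height), mm from box top-left
    cell_mm: float = DEFAULT_CELL_MM

    def __post_init__(self):
        if self.kind not in ("rectangle", "grid"):
            raise ValueError("kind must be 'rectangle' or 'grid'")
        if self.kind == "rectangle" and self.rect_mm is None:
            raise ValueError("rectangle ROI requires rect_mm")
        if self.cell_mm <= 0:
            raise ValueError("cell_mm must be positive")


@dataclass
class RoiMask:
    """Boolean mask over the elastogram box, with grid-cell labels.

    ``cell_id`` is 0 outside all grid cells; cells are labelled 1..n in
    row-major order. For a rectangle ROI all cell ids are 0.
    """

    mask: np.ndarray
    cell_id: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cell_id is None:
            self.cell_id = np.zeros(self.mask.shape, dtype=np.int32)
        self.cell_id = np.asarray(self.cell_id, dtype=np.int32)
        if self.cell_id.shape != self.mask.shape:
            raise ValueError("cell_id must match mask shape")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_cells(self) -> int:
        return int(self.cell_id.max())


def build_rect_mask(geom: ElastogramGeometry, rect_mm) -> RoiMask:
    """Rasterise a physical rectangle into a pixel mask over the box.

    A pixel belongs to the ROI iff its centre falls inside the rectangle
    ``(x0, y0, width, height)`` (mm, x = columns, y = rows, origin at the
    box's top-left corner).
    """
    x0, y0, w, h = (float(v) for v in rect_mm)
    if w <= 0 or h <= 0:
        raise ValueError(f"rectangle {rect_mm} has non-positive size")
    if x0 < 0 or y0 < 0:
        raise ValueError(f"rectangle {rect_mm} extends before the box origin")
    eps = 1e-9 * max(geom.width_mm, geom.height_mm)
    if x0 + w > geom.width_mm + eps or y0 + h > geom.height_mm + eps:
        raise ValueError(
            f"rectangle {rect_mm} extends past the elastogram's "
            f"{geom.width_mm:.3g} x {geom.height_mm:.3g} mm extent")
    H, W = geom.height_px, geom.width_px
    yc = (np.arange(H) + 0.5) * geom.mm_per_px
    xc = (np.arange(W) + 0.5) * geom.mm_per_px
    in_y = (yc >= y0) & (yc < y0 + h)
    in_x = (xc >= x0) & (xc < x0 + w)
    mask = in_y[:, np.newaxis] & in_x[np.newaxis, :]
    if not mask.any():
        raise ValueError(f"rectangle {rect_mm} covers no pixel centres at "
                         f"{geom.mm_per_px} mm/px")
    return RoiMask(mask=mask)


def build_grid(geom: ElastogramGeometry, cell_mm: float = DEFAULT_CELL_MM) -> RoiMask:
    """Tile the box with complete square cells of side ``cell_mm``.

    The cell side is ``round(cell_mm / mm_per_px)`` pixels; cells are tiled
    from the top-left corner and labelled row-major starting at 1. Cells that
    would not fit completely inside the box are dropped.
    """
    if cell_mm <= 0:
        raise ValueError("cell_mm must be positive")
    cell_px = int(round(cell_mm / geom.mm_per_px))
    H, W = geom.height_px, geom.width_px
    if cell_px < 1:
        raise ValueError(f"cell size {cell_mm} mm is below one pixel at "
                         f"{geom.mm_per_px} mm/px")
    n_rows, n_cols = H // cell_px, W // cell_px
    if n_rows == 0 or n_cols == 0:
        raise ValueError(
            f"no complete {cell_mm} mm cell fits in the "
            f"{geom.width_mm:.3g} x {geom.height_mm:.3g} mm elastogram; "
            "use a manual rectangle ROI instead")
    cell_id = np.zeros((H, W), dtype=np.int32)
    label = 1
    for r in range(n_rows):
        for c in range(n_cols):
            cell_id[r * cell_px:(r + 1) * cell_px,
                    c * cell_px:(c + 1) * cell_px] = label
            label += 1
    return RoiMask(mask=cell_id > 0, cell_id=cell_id)


def build_roi(geom: ElastogramGeometry, spec: RoiSpec) -> RoiMask:
    """Dispatch on the ROI kind."""
    if spec.kind == "rectangle":
        return build_rect_mask(geom, spec.rect_mm)
    return build_grid(geom, spec.cell_mm)
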