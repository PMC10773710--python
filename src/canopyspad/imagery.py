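"""Plot-mean reflectance extraction from multiband reflectance rasters.

Field plots are represented in a stitched reflectance mosaic by
rectangular regions of interest (ROIs, conventionally 100×100 pixels);
the plot's reflectance in each band is the arithmetic mean over the
ROI's valid pixels.  This module reads/writes 5-band float32 TIFF
rasters (band order blue, green, red, red_edge, nir), extracts ROI
means, and builds synthetic fixture rasters with known block means so
the extraction path is testable end to end.

Pixel conventions: 0-based, row-major, top-left origin; an ROI covers
the half-open window [row, row+height) × [col, col+width).  Nodata
pixels (encoded as NaN, or as a user-supplied marker value) are
excluded from means; a plot whose ROI is entirely nodata in any band is
flagged missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .indices import BANDS, PlotReflectance

__all__ = [
    "ROISpec",
    "ReflectanceRaster",
    "extract_roi_means",
    "make_fixture_raster",
    "read_raster",
    "write_raster",
    "read_rois",
    "write_rois",
]

log = logging.getLogger(__name__)

MAX_RASTER_DIM = 2000


@dataclass(frozen=True)
class ROISpec:
    """Rectangular plot region: top-left (row, col) plus height × width."""

    plot_id: str
    row: int
    col: int
    height: int = 100
    width: int = 100

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI {self.plot_id}: height/width must be >= 1")
        if self.row < 0 or self.col < 0:
            raise ValueError(f"ROI {self.plot_id}: origin must be non-negative")


@dataclass(frozen=True)
class ReflectanceRaster:
    """Five co-registered fractional-reflectance bands.

    ``data`` has shape (5, rows, cols) in band order blue, green, red,
    red_edge, nir; nodata is carried as NaN internally.  Grids are held
    in float64 so in-memory round trips are exact; the TIFF interchange
    format is float32 (single-precision accuracy on disk).
    """

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] != len(BANDS):
            raise ValueError(
                f"raster must have shape (5, rows, cols), got {arr.shape}"
            )
        valid = arr[np.isfinite(arr)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("reflectance values must lie in [0, 1] or be nodata")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def band(self, name: str) -> np.ndarray:
        return self.data[BANDS.index(name)]


def extract_roi_means(
    raster: ReflectanceRaster,
    rois: Sequence[ROISpec],
    stage: str = "",
) -> tuple[list[PlotReflectance], list[str]]:
    """Per-ROI, per-band means over valid (non-nodata) pixels.

    Returns ``(reflectances, missing_plot_ids)``: plots with an
    all-nodata ROI in any band are reported in the second list rather
    than silently dropped.  Out-of-bounds ROIs raise, naming the plot.
    """
    rows, cols = raster.shape
    out: list[PlotReflectance] = []
    missing: list[str] = []
    for roi in rois:
        if roi.row + roi.height > rows or roi.col + roi.width > cols:
            raise ValueError(
                f"ROI for plot {roi.plot_id!r} exceeds raster bounds "
                f"({rows}x{cols})"
            )
        window = raster.data[
            :, roi.row : roi.row + roi.height, roi.col : roi.col + roi.width
        ]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # an all-nodata band yields NaN, handled as "missing" below
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(window.reshape(len(BANDS), -1), axis=1)
        if not np.all(np.isfinite(means)):
            log.warning("plot %s: all-nodata ROI in at least one band", roi.plot_id)
            missing.append(roi.plot_id)
            continue
        out.append(
            PlotReflectance(
                plot_id=roi.plot_id,
                stage=stage,
                **{band: float(m) for band, m in zip(BANDS, means)},
            )
        )
    return out, missing


def make_fixture_raster(
    plot_values: Mapping[str, Mapping[str, float]],
    *,
    roi_size: tuple[int, int] = (100, 100),
    gap: int = 10,
    columns: int | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ReflectanceRaster, list[ROISpec]]:
    """Tile per-plot constant reflectance blocks into a test raster.

    ``plot_values`` maps plot_id → {band: reflectance}.  Blocks are laid
    out on a grid with ``gap`` pixels of nodata between them; optional
    Gaussian pixel noise (clipped to [0, 1]) is added per band.  The
    block mean equals the requested value exactly when noiseless, and
    within sampling error (~sd/sqrt(pixels)) when noisy.  Deterministic
    for a given seed.
    """
    if not plot_values:
        raise ValueError("no plots supplied")
    h, w = roi_size
    n = len(plot_values)
    ncol = columns if columns is not None else int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    rows = nrow * (h + gap) + gap
    cols = ncol * (w + gap) + gap
    if rows > MAX_RASTER_DIM or cols > MAX_RASTER_DIM:
        raise ValueError(
            f"layout {rows}x{cols} exceeds the {MAX_RASTER_DIM} pixel limit"
        )

    data = np.full((len(BANDS), rows, cols), np.nan, dtype=np.float64)
    rois: list[ROISpec] = []
    rng = np.random.default_rng(seed)
    for k, (plot_id, bands) in enumerate(plot_values.items()):
        r0 = gap + (k // ncol) * (h + gap)
        c0 = gap + (k % ncol) * (w + gap)
        for bi, band in enumerate(BANDS):
            block = np.full((h, w), bands[band], dtype=np.float64)
            if pixel_noise_sd > 0:
                block = block + rng.normal(0.0, pixel_noise_sd, size=(h, w))
            data[bi, r0 : r0 + h, c0 : c0 + w] = np.clip(block, 0.0, 1.0)
        rois.append(ROISpec(plot_id=plot_id, row=r0, col=c0, height=h, width=w))
    return ReflectanceRaster(data), rois


def write_raster(raster: ReflectanceRaster, path: str | Path) -> None:
    """Write the 5 bands as a float32 multiband TIFF (NaN nodata)."""
    tifffile.imwrite(
        str(path), raster.data.astype(np.float32), photometric="minisblack"
    )


def read_raster(path: str | Path, nodata: float | None = None) -> ReflectanceRaster:
    """Read a 5-band float TIFF; an optional nodata value maps to NaN."""
    arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multiband raster, got shape {arr.shape}")
    # accept (rows, cols, 5) layouts from other writers
    if arr.shape[0] != len(BANDS) and arr.shape[-1] == len(BANDS):
        arr = np.moveaxis(arr, -1, 0)
    if arr.shape[0] != len(BANDS):
        raise ValueError(f"{path}: expected {len(BANDS)} bands, got {arr.shape[0]}")
    if nodata is not None:
        arr = np.where(arr == np.float32(nodata), np.nan, arr)
    return ReflectanceRaster(arr)


def write_rois(rois: Iterable[ROISpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"plot_id": r.plot_id, "row": r.row, "col": r.col,
             "height": r.height, "width": r.width}
            for r in rois
        ]
    ).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[ROISpec]:
    df = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", "row", "col", "height", "width"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing ROI columns {sorted(missing)}")
    return [
        ROISpec(
            plot_id=str(r.plot_id), row=int(r.row), col=int(r.col),
            height=int(r.height), width=int(r.width),
        )
        for r in df.itertuples()
    ]
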