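"""Plot-level canopy height from crop surface models.

Per observation date the workflow is: crop surface model (CSM = DSM − DEM),
NGRDI vegetation mask, aggregation of masked CSM pixels by non-overlapping
local-maximum blocks, then the zonal mean of block maxima per plot.  Taking
the mean of local maxima instead of the raw pixel mean keeps every plant in
the plot in the calculation while discarding low-level canopy returns that
would otherwise bias plot height downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import FieldDesign
from .raster import GridMismatchError, RasterGrid

__all__ = ["VegetationMask", "compute_csm", "compute_ngrdi", "binarize_vegetation",
           "aggregate_local_maxima", "zonal_mean_height", "validate_heights"]


@dataclass
class VegetationMask:
    grid: RasterGrid            # boolean-valued raster (0/1)
    source_threshold: float

    @property
    def mask(self) -> np.ndarray:
        return self.grid.values > 0.5


def compute_csm(dsm: RasterGrid, dem: RasterGrid) -> RasterGrid:
    """Crop surface model: cellwise DSM − DEM, clamped at zero.

    Negative differences are DEM noise, not vegetation absence, so they are
    clamped to 0 rather than dropped.  Nodata in either input propagates.
    """
    dsm.require_same_geometry(dem)
    csm = dsm.values - dem.values
    csm = np.where(np.isnan(csm), np.nan, np.clip(csm, 0.0, None))
    return dsm.copy_with(csm)


def compute_ngrdi(green: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Normalized green-red difference index (green − red)/(green + red).

    Negative over bare soil, positive over green canopy.  Cells where
    green + red = 0 become nodata.
    """
    green.require_same_geometry(red)
    g, r = green.values, red.values
    if np.nanmin(g) < 0 or np.nanmin(r) < 0:
        raise ValueError("reflectances must be non-negative")
    denom = g + r
    with np.errstate(invalid="ignore", divide="ignore"):
        ngrdi = np.where(denom > 0, (g - r) / denom, np.nan)
    return green.copy_with(ngrdi)


def binarize_vegetation(ngrdi: RasterGrid, threshold: float = 0.0) -> VegetationMask:
    """Vegetation mask: NGRDI strictly above ``threshold``; nodata → False.

    The default threshold 0 exploits the sign separation: soil NGRDI is
    negative, canopy NGRDI positive.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = np.where(np.isnan(ngrdi.values), 0.0, (ngrdi.values > threshold).astype(float))
    return VegetationMask(ngrdi.copy_with(mask), threshold)


def aggregate_local_maxima(csm: RasterGrid, window: int,
                           mask: VegetationMask | None = None) -> RasterGrid:
    """Block maxima of the (masked) CSM over non-overlapping window x window
    blocks.

    Each block takes the maximum over its masked cells; blocks with no
    masked cell are nodata.  The result is a coarser raster whose cell size
    is ``window`` source cells (trailing partial blocks are included).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_rows, n_cols = csm.values.shape
    if window > max(n_rows, n_cols):
        raise ValueError(f"window {window} larger than raster {csm.values.shape}")
    vals = csm.values.copy()
    if mask is not None:
        csm.require_same_geometry(mask.grid)
        vals = np.where(mask.mask, vals, np.nan)

    nbr = int(np.ceil(n_rows / window))
    nbc = int(np.ceil(n_cols / window))
    padded = np.full((nbr * window, nbc * window), np.nan)
    padded[:n_rows, :n_cols] = vals
    blocks = padded.reshape(nbr, window, nbc, window).transpose(0, 2, 1, 3)
    flat = blocks.reshape(nbr, nbc, -1)
    any_valid = ~np.all(np.isnan(flat), axis=2)
    out = np.full((nbr, nbc), np.nan)
    if np.any(any_valid):
        out[any_valid] = np.nanmax(flat[any_valid], axis=1)

    # block grid keeps the source's top-left (north-west) anchor; origin is
    # the south-west corner of the padded extent
    new_cs = csm.cell_size * window
    x0, y0 = csm.origin
    y_top = y0 + n_rows * csm.cell_size
    return RasterGrid((x0, y_top - nbr * new_cs), new_cs, out)


def zonal_mean_height(blocks: RasterGrid, design: FieldDesign, date: int) -> pd.DataFrame:
    """Mean of block maxima per plot, converted m → cm.

    A block belongs to the plot whose half-open rectangle contains its
    center.  Plots with no usable block get height NaN and
    ``n_pixels_used`` 0.
    """
    if design.n_plots == 0:
        raise ValueError("empty field design")
    xc, yc = blocks.cell_centers()
    plot_idx = design.contains(xc.ravel(), yc.ravel())
    vals = blocks.values.ravel()
    usable = (plot_idx >= 0) & ~np.isnan(vals)

    heights = np.full(design.n_plots, np.nan)
    counts = np.zeros(design.n_plots, dtype=int)
    if np.any(usable):
        idx = plot_idx[usable]
        sums = np.bincount(idx, weights=vals[usable], minlength=design.n_plots)
        counts = np.bincount(idx, minlength=design.n_plots)
        with np.errstate(invalid="ignore"):
            heights = np.where(counts > 0, sums / np.maximum(counts, 1) * 100.0, np.nan)
    return pd.DataFrame({
        "plot_id": design.plot_ids,
        "das": date,
        "height_cm": heights,
        "n_pixels_used": counts,
    })


def validate_heights(estimated: pd.DataFrame, reference: pd.DataFrame) -> dict:
    """OLS regression of estimated on reference heights.

    Both frames need columns plot_id, das, height_cm.  Returns R², RMSE of
    the regression residuals (cm), slope and intercept, and the pair count.
    """
    merged = estimated.merge(reference, on=["plot_id", "das"], suffixes=("_est", "_ref"))
    merged = merged.dropna(subset=["height_cm_est", "height_cm_ref"])
    if len(merged) < 3:
        raise ValueError(f"need >= 3 matched (plot, date) pairs, got {len(merged)}")
    x = merged["height_cm_ref"].to_numpy()
    y = merged["height_cm_est"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "r2": r2,
        "rmse_cm": float(np.sqrt(np.mean(resid**2))),
        "slope": float(slope),
        "intercept": float(intercept),
        "n": int(len(merged)),
    }
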