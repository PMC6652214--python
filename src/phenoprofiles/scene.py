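"""Render synthetic field scenes: terrain, canopy surfaces, spectral bands.

The renderer turns a :class:`~phenoprofiles.design.FieldDesign` plus true
per-plot height trajectories into the rasters a UAV photogrammetry stack
would deliver: a true ground DEM, per-date DSMs, and green/red reflectance
bands, along with dense point clouds sampled from the surfaces.

Plants are flat-topped (truncated) paraboloid crowns placed on the plot's
planting rows at the design's seeding density.  Crown radius grows with
plant height, so early-season scenes expose most of the soil (the regime
the ground classifier needs) while late-season canopies close.  The flat
crown tops sit exactly at the plot's true height, so aggregating the
rendered surface by local maxima recovers the truth on noiseless scenes.

Spectral model: canopy pixels are greener than red, soil pixels redder
than green, so the normalized green-red difference index (NGRDI) is
positive over canopy and negative over soil; only that sign matters
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import FieldDesign
from .pointcloud import GROUND, NON_GROUND, PointCloud
from .raster import RasterGrid

__all__ = ["TerrainParams", "CanopyParams", "SpectralParams", "SyntheticScene",
           "render_scene", "sample_point_cloud"]


@dataclass
class TerrainParams:
    """Smooth terrain: base elevation plus gentle sinusoidal relief (m)."""

    base_elevation_m: float = 50.0
    relief_amplitude_m: float = 0.08
    relief_wavelength_m: float = 40.0
    slope_x: float = 0.0            # m of rise per m east
    slope_y: float = 0.0

    def elevation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        w = 2 * np.pi / self.relief_wavelength_m
        return (
            self.base_elevation_m
            + self.relief_amplitude_m * np.sin(w * x) * np.cos(w * y)
            + self.slope_x * x
            + self.slope_y * y
        )


@dataclass
class CanopyParams:
    """Crown geometry.  Radius grows with height up to ``radius_max_m``;
    the crown is flat (at the plant's full height) inside
    ``flat_fraction * radius`` and falls off parabolically to zero."""

    radius_min_m: float = 0.04
    radius_max_m: float = 0.45
    radius_per_height: float = 0.30
    flat_fraction: float = 0.80

    def radius(self, height_m: float) -> float:
        return float(np.clip(self.radius_min_m + self.radius_per_height * height_m,
                             self.radius_min_m, self.radius_max_m))


@dataclass
class SpectralParams:
    """Band means for the two-class spectral model (reflectance, unitless).

    A pixel renders as vegetation only where the canopy surface reaches
    ``cover_frac`` of the local plant's full height: at crown edges the
    soil background dominates the pixel and its green-red index stays
    negative, as it does in real imagery of open canopies.
    """

    canopy_green: float = 0.35
    canopy_red: float = 0.18
    soil_green: float = 0.20
    soil_red: float = 0.30
    noise_sd: float = 0.0
    cover_frac: float = 0.85


@dataclass
class SyntheticScene:
    """A rendered multi-date scene with full ground truth."""

    design: FieldDesign
    days: tuple[int, ...]
    dem_truth: RasterGrid
    dsm: dict[int, RasterGrid]
    green_band: dict[int, RasterGrid]
    red_band: dict[int, RasterGrid]
    canopy_truth: dict[int, RasterGrid]          # canopy height above ground (m)
    true_plot_heights: pd.DataFrame              # plot x date, cm
    abnormal: pd.Series | None = None
    rng_seed: int = 0

    def write(self, outdir: str | Path) -> dict:
        """Write GeoTIFF rasters, CSV truth tables and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: dict[str, str] = {}

        def _w(grid: RasterGrid, name: str) -> None:
            grid.to_geotiff(outdir / name)
            files[name.split(".")[0]] = name

        _w(self.dem_truth, "dem_truth.tif")
        for d in self.days:
            _w(self.dsm[d], f"dsm_{d:03d}.tif")
            _w(self.green_band[d], f"green_{d:03d}.tif")
            _w(self.red_band[d], f"red_{d:03d}.tif")
        self.design.to_csv(outdir / "plots.csv")
        self.true_plot_heights.to_csv(outdir / "true_heights.csv")
        if self.abnormal is not None:
            self.abnormal.to_frame().to_csv(outdir / "abnormal.csv")
        manifest = {
            "days": list(self.days),
            "rng_seed": self.rng_seed,
            "grid": self.dem_truth.meta_dict(),
            "files": files,
        }
        with open(outdir / "scene_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest


def _plant_positions(design: FieldDesign, plot_index: int) -> np.ndarray:
    """Deterministic planting grid for one plot: rows across the plot width
    at the design row spacing, plants along the length at the seeding
    density."""
    x0, y0, x1, y1 = design.rects[plot_index]
    width, length = x1 - x0, y1 - y0
    n_rows = max(1, int(round(width / design.row_spacing_m)))
    row_margin = (width - (n_rows - 1) * design.row_spacing_m) / 2
    rows_x = x0 + row_margin + design.row_spacing_m * np.arange(n_rows)

    n_plants = max(n_rows, int(round(design.seeding_density * width * length)))
    per_row = int(np.ceil(n_plants / n_rows))
    dy = length / per_row
    ys = y0 + dy * (np.arange(per_row) + 0.5)
    xx, yy = np.meshgrid(rows_x, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _paint_crowns(canopy: np.ndarray, grid: RasterGrid, positions: np.ndarray,
                  height_m: float, params: CanopyParams,
                  peak: np.ndarray | None = None) -> None:
    """Paint flat-topped paraboloid crowns into ``canopy`` (max-composited).

    ``peak``, when given, records the full plant height over each crown's
    footprint (used to decide spectral vegetation cover).
    """
    if height_m <= 0:
        return
    cs = grid.cell_size
    x0, y0 = grid.origin
    n_rows, n_cols = canopy.shape
    radius = params.radius(height_m)
    r_flat = params.flat_fraction * radius
    ncell = max(1, int(np.ceil(radius / cs)) + 1)
    for px, py in positions:
        # raster indices of the crown's bounding window (row 0 = north)
        ci = int((px - x0) / cs)
        ri = int(n_rows - 1 - (py - y0) / cs)
        r_lo, r_hi = max(0, ri - ncell), min(n_rows, ri + ncell + 1)
        c_lo, c_hi = max(0, ci - ncell), min(n_cols, ci + ncell + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        xs = x0 + (np.arange(c_lo, c_hi) + 0.5) * cs
        ys = y0 + (n_rows - np.arange(r_lo, r_hi) - 0.5) * cs
        dx = xs[None, :] - px
        dy = ys[:, None] - py
        rr = np.hypot(dx, dy)
        bump = np.zeros_like(rr)
        bump[rr <= r_flat] = height_m
        shoulder = (rr > r_flat) & (rr < radius)
        frac = (rr[shoulder] - r_flat) / max(radius - r_flat, 1e-9)
        bump[shoulder] = height_m * (1.0 - frac**2)
        window = canopy[r_lo:r_hi, c_lo:c_hi]
        np.maximum(window, bump, out=window)
        if peak is not None:
            pwin = peak[r_lo:r_hi, c_lo:c_hi]
            np.maximum(pwin, np.where(rr < radius, height_m, 0.0), out=pwin)


def render_scene(
    design: FieldDesign,
    true_heights: pd.DataFrame,
    terrain: TerrainParams | None = None,
    canopy: CanopyParams | None = None,
    spectral: SpectralParams | None = None,
    cell_size_m: float = 0.025,
    margin_m: float = 1.0,
    seed: int = 0,
    abnormal: pd.Series | None = None,
) -> SyntheticScene:
    """Render DEM, per-date DSMs and green/red bands for a field design.

    ``true_heights`` is the plot x day matrix in cm (as produced by
    :func:`~phenoprofiles.growth.simulate_growth_profiles`).
    """
    if cell_size_m <= 0:
        raise ValueError("cell_size_m must be positive")
    if cell_size_m >= min(design.plot_width_m, design.plot_length_m):
        raise ValueError("cell size must be smaller than the plot dimensions")
    terrain = terrain or TerrainParams()
    canopy = canopy or CanopyParams()
    spectral = spectral or SpectralParams()
    rng = np.random.default_rng(seed)

    bx0, by0, bx1, by1 = design.bounds
    x0, y0 = bx0 - margin_m, by0 - margin_m
    n_cols = int(np.ceil((bx1 - x0 + margin_m) / cell_size_m))
    n_rows = int(np.ceil((by1 - y0 + margin_m) / cell_size_m))

    grid0 = RasterGrid((x0, y0), cell_size_m, np.zeros((n_rows, n_cols)))
    xc, yc = grid0.cell_centers()
    dem_vals = terrain.elevation(xc, yc)
    dem_truth = grid0.copy_with(dem_vals)

    days = tuple(int(c) for c in true_heights.columns)
    positions = [_plant_positions(design, i) for i in range(design.n_plots)]

    dsm, green_b, red_b, canopy_t = {}, {}, {}, {}
    for d in days:
        canopy_vals = np.zeros((n_rows, n_cols))
        peak_vals = np.zeros((n_rows, n_cols))
        for i, pid in enumerate(design.plot_ids):
            h_cm = float(true_heights.loc[pid, d]) if pid in true_heights.index else 0.0
            _paint_crowns(canopy_vals, grid0, positions[i], h_cm / 100.0, canopy,
                          peak=peak_vals)
        dsm[d] = grid0.copy_with(dem_vals + canopy_vals)
        canopy_t[d] = grid0.copy_with(canopy_vals)

        veg = (canopy_vals > 0) & (canopy_vals >= spectral.cover_frac * peak_vals)
        g = np.where(veg, spectral.canopy_green, spectral.soil_green)
        r = np.where(veg, spectral.canopy_red, spectral.soil_red)
        if spectral.noise_sd > 0:
            g = g + spectral.noise_sd * rng.standard_normal(g.shape)
            r = r + spectral.noise_sd * rng.standard_normal(r.shape)
        green_b[d] = grid0.copy_with(np.clip(g, 1e-6, None))
        red_b[d] = grid0.copy_with(np.clip(r, 1e-6, None))

    truth_cm = true_heights.loc[design.plot_ids, list(days)].astype(float)
    return SyntheticScene(
        design=design, days=days, dem_truth=dem_truth, dsm=dsm,
        green_band=green_b, red_band=red_b, canopy_truth=canopy_t,
        true_plot_heights=truth_cm, abnormal=abnormal, rng_seed=seed,
    )


def _bilinear(grid: RasterGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear sample of a raster at arbitrary points (cell-center reg.)."""
    cs = grid.cell_size
    x0, y0 = grid.origin
    n_rows, n_cols = grid.values.shape
    fc = np.clip((x - x0) / cs - 0.5, 0, n_cols - 1)
    fr = np.clip(n_rows - 1 - ((y - y0) / cs - 0.5), 0, n_rows - 1)
    c0 = np.clip(np.floor(fc).astype(int), 0, n_cols - 2) if n_cols > 1 else np.zeros_like(fc, int)
    r0 = np.clip(np.floor(fr).astype(int), 0, n_rows - 2) if n_rows > 1 else np.zeros_like(fr, int)
    tc = fc - c0
    tr = fr - r0
    v = grid.values
    if n_cols == 1:
        tc = np.zeros_like(tc)
    if n_rows == 1:
        tr = np.zeros_like(tr)
    c1 = np.minimum(c0 + 1, n_cols - 1)
    r1 = np.minimum(r0 + 1, n_rows - 1)
    return ((1 - tr) * ((1 - tc) * v[r0, c0] + tc * v[r0, c1])
            + tr * ((1 - tc) * v[r1, c0] + tc * v[r1, c1]))


def sample_point_cloud(
    scene: SyntheticScene,
    day: int,
    density_per_cm2: float = 0.05,
    vertical_noise_sd_cm: float = 0.0,
    seed: int = 0,
) -> PointCloud:
    """Sample a dense point cloud from one date's surface.

    Points fall uniformly over the scene footprint; count is Poisson with
    mean ``density * area``.  Each point takes the surface height at its
    location — ground where soil is exposed, canopy elsewhere — plus
    optional vertical noise.  True class labels are attached.
    """
    if density_per_cm2 <= 0:
        raise ValueError("density must be positive")
    if day not in scene.dsm:
        raise KeyError(f"scene has no date {day}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = scene.dem_truth.bounds
    area_cm2 = (xmax - xmin) * (ymax - ymin) * 1e4
    n = int(rng.poisson(density_per_cm2 * area_cm2))
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    canopy_h = _bilinear(scene.canopy_truth[day], xs, ys)
    zg = _bilinear(scene.dem_truth, xs, ys)
    zs = zg + canopy_h
    if vertical_noise_sd_cm > 0:
        zs = zs + (vertical_noise_sd_cm / 100.0) * rng.standard_normal(n)
    labels = np.where(canopy_h > 1e-6, NON_GROUND, GROUND)
    return PointCloud(np.column_stack([xs, ys, zs]), labels)
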