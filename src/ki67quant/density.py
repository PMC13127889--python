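"""Cell-density rasters and the labeling-index ratio map.

Density at a grid point is the number of classified nuclei within a 50 μm
search radius, divided by the disk area — a flat-kernel density in cells
per mm² that honors the literal search-radius semantics.  The LI map is the
cellwise ratio of positive to total density, highlighting proliferative
regions without the confound of absolute cellularity.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclasses.dataclass
class DensityMap:
    grid: np.ndarray                # (H, W) float; cells/mm² or ratio; NaN = NA
    grid_mpp: float                 # μm per map pixel
    origin_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 50.0
    class_label: str = "positive"   # positive | negative | li_ratio

    def same_geometry(self, other: "DensityMap") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and abs(self.grid_mpp - other.grid_mpp) < 1e-9
            and self.origin_um == other.origin_um
        )


def compute_density_map(
    points: np.ndarray | list[tuple[float, float]],
    extent_um: tuple[float, float],
    grid_mpp: float = 8.0,
    radius_um: float = 50.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
    class_label: str = "positive",
    kernel: str = "disk",
) -> DensityMap:
    """Kernel density of point detections in cells per mm².

    With the default ``disk`` kernel, grid cell value = (points within
    ``radius_um`` of the cell center, boundary inclusive, Euclidean) /
    (π·radius²) — the literal search-radius semantics.  ``kernel="gaussian"``
    instead spreads each point over a normalized Gaussian with sigma =
    radius/2, preserving total mass while smoothing the plateau edges.
    ``extent_um`` is the slide (width, height) in μm.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if kernel not in {"disk", "gaussian"}:
        raise ValueError(f"unknown kernel {kernel!r}")
    w_um, h_um = extent_um
    n_cols = max(1, int(math.ceil(w_um / grid_mpp)))
    n_rows = max(1, int(math.ceil(h_um / grid_mpp)))
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    disk_area_mm2 = math.pi * (radius_um / 1000.0) ** 2

    if len(pts) == 0:
        grid = np.zeros((n_rows, n_cols))
    elif kernel == "gaussian":
        from scipy import ndimage

        ox, oy = origin_um
        hist = np.zeros((n_rows, n_cols))
        cols = np.clip(((pts[:, 0] - ox) / grid_mpp).astype(int), 0, n_cols - 1)
        rows = np.clip(((pts[:, 1] - oy) / grid_mpp).astype(int), 0, n_rows - 1)
        np.add.at(hist, (rows, cols), 1.0)
        sigma_px = (radius_um / 2.0) / grid_mpp
        px_mm2 = (grid_mpp / 1000.0) ** 2
        grid = ndimage.gaussian_filter(hist, sigma_px, mode="constant") / px_mm2
    else:
        ox, oy = origin_um
        xs = ox + (np.arange(n_cols) + 0.5) * grid_mpp
        ys = oy + (np.arange(n_rows) + 0.5) * grid_mpp
        centers = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        tree = cKDTree(pts)
        # cKDTree query_ball_point is boundary-inclusive up to fp rounding;
        # pad the radius by one ulp-scale epsilon to keep it that way.
        counts = tree.query_ball_point(
            centers, r=radius_um * (1 + 1e-12), return_length=True
        )
        grid = counts.reshape(n_rows, n_cols) / disk_area_mm2

    return DensityMap(
        grid=grid.astype(float),
        grid_mpp=grid_mpp,
        origin_um=origin_um,
        radius_um=radius_um,
        class_label=class_label,
    )


def compute_li_map(pos: DensityMap, neg: DensityMap) -> DensityMap:
    """Cellwise positive/(positive+negative); NaN where no cells are in reach."""
    if not pos.same_geometry(neg):
        raise ValueError("positive and negative maps must share grid geometry")
    total = pos.grid + neg.grid
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, pos.grid / total, np.nan)
    return DensityMap(
        grid=ratio,
        grid_mpp=pos.grid_mpp,
        origin_um=pos.origin_um,
        radius_um=pos.radius_um,
        class_label="li_ratio",
    )


def normalize_and_render(
    dmap: DensityMap,
    colormap_name: str = "jet",
    background_rgb: tuple[int, int, int] = (255, 255, 255),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max normalize over non-NA cells and apply a matplotlib colormap.

    NA cells render as the background color and are excluded from the scale.
    Returns (8-bit RGB raster, (min, max) scale for the color bar).  A
    constant map renders at the colormap midpoint.
    """
    import matplotlib

    grid = dmap.grid
    valid = np.isfinite(grid)
    if not valid.any():
        raise ValueError("all-NA map cannot be rendered")
    vmin, vmax = float(grid[valid].min()), float(grid[valid].max())
    if vmax - vmin < 1e-30:
        norm = np.full_like(grid, 0.5)
    else:
        norm = (grid - vmin) / (vmax - vmin)
    cmap = matplotlib.colormaps[colormap_name]
    rgba = cmap(np.where(valid, norm, 0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~valid] = np.array(background_rgb, dtype=np.uint8)
    return rgb, (vmin, vmax)


def save_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Save the raw map as 16-bit grayscale TIFF with a JSON scale sidecar.

    The sidecar records the linear scale (vmin, vmax), grid resolution and
    radius so the raw values are recoverable from the integer raster.
    """
    import tifffile

    path = Path(path)
    valid = np.isfinite(dmap.grid)
    vmax = float(dmap.grid[valid].max()) if valid.any() else 0.0
    vmin = 0.0
    scale = (vmax - vmin) or 1.0
    raw = np.zeros_like(dmap.grid)
    raw[valid] = (dmap.grid[valid] - vmin) / scale
    tifffile.imwrite(path, np.round(raw * 65535).astype(np.uint16))
    sidecar = {
        "vmin": vmin,
        "vmax": vmax,
        "grid_mpp": dmap.grid_mpp,
        "radius_um": dmap.radius_um,
        "class_label": dmap.class_label,
        "origin_um": list(dmap.origin_um),
        "na_value": 0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
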