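"""Two-stage tissue segmentation at a coarse pixel-classifier resolution.

Stage one removes artifacts (pen marks, debris, dark smudges) with a fixed
red-channel threshold; stage two refines the tumor-tissue mask with a
stain-adaptive custom threshold derived from the estimated background and
the weak-hematoxylin flag.  Both stages run on a 4.0016 μm/px working grid
with a Gaussian prefilter (sigma 8 px) and area/hole filters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure

from .stains import StainModel
from .wsi_io import SlideImage, resample_to_mpp

WORKING_MPP = 4.0016           # μm per pixel of the classifier grid
GAUSSIAN_SIGMA_PX = 8.0
PRELIM_THRESHOLD = 80.0        # red intensity; above = tissue/region
PRELIM_MIN_AREA_UM2 = 20_000.0
REFINED_MIN_AREA_UM2 = 10_000.0
MIN_HOLE_AREA_UM2 = 8_000.0

_EIGHT = np.ones((3, 3), dtype=int)   # 8-connectivity for components and holes


@dataclasses.dataclass
class TissueMask:
    """Binary tissue mask at the working resolution, with component geometry."""

    mask: np.ndarray               # (H, W) bool
    mpp: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def component_areas_um2(self) -> list[float]:
        labels, n = ndimage.label(self.mask, structure=_EIGHT)
        if n == 0:
            return []
        counts = np.bincount(labels.ravel())[1:]
        return [float(c) * self.mpp**2 for c in counts]

    @property
    def total_area_mm2(self) -> float:
        return float(self.mask.sum()) * self.mpp**2 / 1e6

    def polygons(self) -> list[np.ndarray]:
        """Component outlines in μm (slide frame), via marching squares."""
        padded = np.pad(self.mask.astype(float), 1)
        ox, oy = self.origin_um
        polys = []
        for contour in measure.find_contours(padded, 0.5):
            # contour rows are (y, x) in padded pixel coords
            xy = np.stack(
                [(contour[:, 1] - 1) * self.mpp + ox,
                 (contour[:, 0] - 1) * self.mpp + oy],
                axis=1,
            )
            polys.append(xy)
        return polys

    def contains_um(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Vectorized membership test for slide-frame μm points."""
        ox, oy = self.origin_um
        col = np.floor((np.asarray(x_um) - ox) / self.mpp).astype(int)
        row = np.floor((np.asarray(y_um) - oy) / self.mpp).astype(int)
        inside = (
            (row >= 0) & (row < self.mask.shape[0])
            & (col >= 0) & (col < self.mask.shape[1])
        )
        out = np.zeros_like(inside)
        out[inside] = self.mask[row[inside], col[inside]]
        return out


def export_mask_geojson(mask: TissueMask, path, classification: str = "Tumor") -> None:
    """Write mask component outlines as GeoJSON annotation polygons (μm)."""
    import json

    features = []
    for poly in mask.polygons():
        ring = [[float(x), float(y)] for x, y in poly]
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "objectType": "annotation",
                    "classification": {"name": classification},
                },
            }
        )
    from pathlib import Path

    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def export_mask_png(mask: TissueMask, path) -> None:
    """Write the binary mask as an 8-bit PNG at the working resolution."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))


def filter_components(
    mask: np.ndarray,
    mpp: float,
    min_area_um2: float,
    min_hole_area_um2: float,
) -> np.ndarray:
    """Drop small foreground components and fill small interior holes.

    Components and holes use 8-connectivity; the comparison keeps areas
    ``>= min_area`` (a component of exactly the minimum survives).  A hole is
    a background component that does not touch the raster border.  The
    operation is idempotent.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    mask = np.asarray(mask, dtype=bool)
    px_area = mpp * mpp

    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n:
        counts = np.bincount(labels.ravel())
        keep = counts * px_area >= min_area_um2
        keep[0] = False
        mask = keep[labels]

    bg_labels, n_bg = ndimage.label(~mask, structure=_EIGHT)
    if n_bg:
        border = np.unique(
            np.concatenate(
                [bg_labels[0], bg_labels[-1], bg_labels[:, 0], bg_labels[:, -1]]
            )
        )
        counts = np.bincount(bg_labels.ravel())
        fill = counts * px_area < min_hole_area_um2
        fill[0] = False
        fill[border] = False
        mask = mask | fill[bg_labels]
    return mask


def _smoothed_red(slide: SlideImage, working_mpp: float, sigma: float) -> tuple[np.ndarray, SlideImage]:
    work = resample_to_mpp(slide, working_mpp)
    red = ndimage.gaussian_filter(
        work.pixel_data[:, :, 0].astype(float), sigma=sigma, mode="reflect"
    )
    # strict threshold comparisons must not flip on 1e-13 filter jitter
    return np.round(red, 6), work


def segment_preliminary(
    slide: SlideImage,
    working_mpp: float = WORKING_MPP,
    threshold: float = PRELIM_THRESHOLD,
    sigma: float = GAUSSIAN_SIGMA_PX,
    min_area_um2: float = PRELIM_MIN_AREA_UM2,
    min_hole_area_um2: float = MIN_HOLE_AREA_UM2,
) -> TissueMask:
    """Artifact-removing first pass: keep smoothed red strictly above threshold.

    Dark artifacts (pen marks, debris) fall below the fixed red threshold and
    are excluded; glass background stays in at this stage and is removed by
    the refined pass.
    """
    red, work = _smoothed_red(slide, working_mpp, sigma)
    mask = red > threshold
    mask = filter_components(mask, work.mpp, min_area_um2, min_hole_area_um2)
    return TissueMask(mask=mask, mpp=work.mpp, origin_um=slide.origin_um)


def compute_custom_threshold(
    model: StainModel,
    background_red: int | None = None,
    margin_strong: float = 40.0,
    margin_weak: float = 15.0,
    clamp: tuple[float, float] = (10.0, 250.0),
) -> float:
    """Stain-adaptive red threshold for the refined tissue pass.

    Strong hematoxylin lets the threshold sit well below the background red
    value; weakly stained slides barely darken the red channel, so a higher
    threshold (smaller margin) is applied to keep faint tissue in the mask.
    """
    if background_red is None:
        background_red = model.background_rgb[0]
    margin = margin_weak if model.weak_hematoxylin else margin_strong
    return float(np.clip(background_red - margin, *clamp))


def segment_refined(
    slide: SlideImage,
    threshold: float,
    preliminary: TissueMask | None = None,
    working_mpp: float = WORKING_MPP,
    sigma: float = GAUSSIAN_SIGMA_PX,
    min_area_um2: float = REFINED_MIN_AREA_UM2,
    min_hole_area_um2: float = MIN_HOLE_AREA_UM2,
) -> TissueMask:
    """Tumor-tissue pass: smoothed red strictly below the custom threshold.

    The result is intersected with the preliminary mask so artifacts removed
    there never re-enter, guaranteeing refined ⊆ preliminary.
    """
    if not 10.0 <= threshold <= 250.0:
        raise ValueError(f"threshold {threshold} outside [10, 250]")
    if preliminary is None:
        preliminary = segment_preliminary(slide, working_mpp=working_mpp, sigma=sigma)
    red, work = _smoothed_red(slide, working_mpp, sigma)
    mask = (red < threshold) & preliminary.mask
    mask = filter_components(mask, work.mpp, min_area_um2, min_hole_area_um2)
    # Hole filling may re-admit pixels the preliminary pass excluded (e.g. a
    # small removed bright island); intersect again so refined ⊆ preliminary
    # holds unconditionally.
    mask &= preliminary.mask
    return TissueMask(mask=mask, mpp=work.mpp, origin_um=slide.origin_um)
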