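"""Slide input/output: calibrated rasters, tiling, and pipeline writers.

Slides are brightfield RGB rasters with a microns-per-pixel (mpp)
calibration.  Pyramidal TIFF/OME-TIFF files are read through :mod:`tifffile`
(levels discovered from the series); flat PNG/TIFF fixtures are read with an
mpp supplied by a ``<file>.mpp.json`` sidecar or an explicit override.

Coordinate convention: pixel-centered, 0-based, x rightward / y downward.
All exported geometry is in μm in the full-slide frame so detections overlay
correctly in slide viewers.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .stats import SlideSummary


class CalibrationError(ValueError):
    """Raised when a slide has no resolution metadata and no override."""


@dataclasses.dataclass
class SlideImage:
    """An RGB slide raster with physical calibration.

    ``pixel_data`` holds the working level; ``levels`` optionally describes
    further pyramid levels as ``(mpp, array)`` pairs, finest first.
    """

    pixel_data: np.ndarray          # (H, W, 3) uint8
    mpp: float                      # μm per pixel, isotropic
    slide_id: str = "slide"
    origin_um: tuple[float, float] = (0.0, 0.0)   # slide-frame offset of pixel (0, 0)
    levels: list[tuple[float, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if self.pixel_data.ndim != 3 or self.pixel_data.shape[2] != 3:
            raise ValueError("pixel_data must be an (H, W, 3) RGB raster")

    @property
    def width(self) -> int:
        return self.pixel_data.shape[1]

    @property
    def height(self) -> int:
        return self.pixel_data.shape[0]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) in μm."""
        return (self.width * self.mpp, self.height * self.mpp)


@dataclasses.dataclass
class Tile:
    """One tile of a slide at a fixed resolution.

    ``core`` is the interior rectangle ``(x0, y0, x1, y1)`` in slide-frame
    pixels at the tile's resolution; cores of a tiling partition the slide,
    while tile rasters extend ``overlap`` pixels beyond their core.
    """

    pixel_data: np.ndarray
    origin: tuple[int, int]         # (x, y) pixel offset of raster in slide frame
    mpp: float
    core: tuple[int, int, int, int]


def nearest_at_or_finer(level_mpps: Sequence[float], target_mpp: float) -> int:
    """Index of the coarsest pyramid level whose mpp does not exceed the target.

    Falls back to the finest level when every level is coarser than requested
    (upsampling blurs threshold operations, so we never pick a coarser one).
    """
    candidates = [i for i, m in enumerate(level_mpps) if m <= target_mpp]
    if not candidates:
        return int(np.argmin(level_mpps))
    return max(candidates, key=lambda i: level_mpps[i])


def _mpp_from_tiff(tif) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)  # enum or raw int
    if unit == 3:       # pixels per centimeter
        return 1e4 * den / num
    if unit == 2:       # pixels per inch
        return 25400.0 * den / num
    return None


def read_slide(
    path: str | Path,
    target_mpp: float | None = None,
    mpp: float | None = None,
    slide_id: str | None = None,
) -> SlideImage:
    """Read a slide raster with physical calibration.

    Resolution is taken from TIFF tags, else a ``<file>.mpp.json`` sidecar,
    else the ``mpp`` override.  When ``target_mpp`` is given, the pyramid
    level nearest at-or-finer is selected and its effective mpp recorded.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slide file not found: {path}")
    slide_id = slide_id or path.stem

    sidecar = path.with_name(path.name + ".mpp.json")
    sidecar_mpp = None
    if sidecar.exists():
        sidecar_mpp = float(json.loads(sidecar.read_text())["mpp"])

    suffix = path.suffix.lower()
    levels: list[tuple[float, np.ndarray]] = []
    if suffix in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            base_mpp = mpp or sidecar_mpp or _mpp_from_tiff(tif)
            if base_mpp is None:
                raise CalibrationError(
                    f"no resolution metadata in {path} and no mpp override given"
                )
            series = tif.series[0]
            arrays = [lvl.asarray() for lvl in series.levels] if series.levels else [
                series.asarray()
            ]
            base_w = arrays[0].shape[1]
            for arr in arrays:
                arr = _as_rgb(arr)
                levels.append((base_mpp * base_w / arr.shape[1], arr))
    else:
        import imageio.v3 as iio

        arr = _as_rgb(iio.imread(path))
        base_mpp = mpp or sidecar_mpp
        if base_mpp is None:
            raise CalibrationError(
                f"no resolution metadata in {path} and no mpp override given"
            )
        levels.append((float(base_mpp), arr))

    if target_mpp is None:
        idx = 0
    else:
        idx = nearest_at_or_finer([m for m, _ in levels], target_mpp)
    eff_mpp, data = levels[idx]
    return SlideImage(
        pixel_data=data, mpp=eff_mpp, slide_id=slide_id, levels=levels or None
    )


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def resample_to_mpp(slide: SlideImage, target_mpp: float) -> SlideImage:
    """Area-average resample of a slide raster to ``target_mpp``.

    A no-op when the target matches the current calibration within 1e-9.
    Downsampling is anti-aliased (area averaging); physical extent is
    preserved to within one output pixel.
    """
    if abs(target_mpp - slide.mpp) < 1e-9:
        return slide
    scale = slide.mpp / target_mpp
    out_h = max(1, round(slide.height * scale))
    out_w = max(1, round(slide.width * scale))
    out = resize(
        slide.pixel_data.astype(float),
        (out_h, out_w, 3),
        order=1,
        anti_aliasing=scale < 1,
        preserve_range=True,
    )
    return SlideImage(
        pixel_data=np.clip(np.rint(out), 0, 255).astype(np.uint8),
        mpp=target_mpp,
        slide_id=slide.slide_id,
        origin_um=slide.origin_um,
    )


def crop_control_tissue(
    slide: SlideImage, fraction: float = 0.5, side: str = "left"
) -> SlideImage:
    """Drop the left ``fraction`` of the slide where control tissue sits.

    Control tissue is a known-positive reference block mounted beside the
    specimen; it must not contribute to the labeling index, so only the
    right side is analyzed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if side != "left":
        raise ValueError("only left-side control tissue is supported")
    x0 = int(round(fraction * slide.width))
    ox, oy = slide.origin_um
    return SlideImage(
        pixel_data=slide.pixel_data[:, x0:, :],
        mpp=slide.mpp,
        slide_id=slide.slide_id,
        origin_um=(ox + x0 * slide.mpp, oy),
    )


def iter_tiles(
    slide: SlideImage, target_mpp: float, tile_px: int, overlap_px: int = 0
) -> Iterator[Tile]:
    """Stream overlapping tiles whose cores partition the slide.

    Core blocks have side ``tile_px − 2·overlap_px``; each tile raster is its
    core expanded by ``overlap_px`` on every side, clipped to the slide, so
    an object near a core edge is fully visible in at least one tile.
    """
    if overlap_px < 0 or tile_px <= 2 * overlap_px:
        raise ValueError("require tile_px > 2*overlap_px >= 0")
    work = resample_to_mpp(slide, target_mpp)
    h, w = work.height, work.width
    step = tile_px - 2 * overlap_px
    for cy in range(0, h, step):
        for cx in range(0, w, step):
            core = (cx, cy, min(cx + step, w), min(cy + step, h))
            x0 = max(0, core[0] - overlap_px)
            y0 = max(0, core[1] - overlap_px)
            x1 = min(w, core[2] + overlap_px)
            y1 = min(h, core[3] + overlap_px)
            yield Tile(
                pixel_data=work.pixel_data[y0:y1, x0:x1],
                origin=(x0, y0),
                mpp=work.mpp,
                core=core,
            )


# ---------------------------------------------------------------------------
# Writers

def write_detections(nuclei, path: str | Path) -> None:
    """Write detections as a GeoJSON FeatureCollection (μm coordinates).

    Each feature carries a closed polygon ring, the classification
    ("Positive"/"Negative"), the centroid, and the mean-DAB measurement —
    the layout slide viewers expect for overlay import.
    """
    features = []
    for nuc in nuclei:
        ring = [list(map(float, v)) for v in nuc.polygon]
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "objectType": "detection",
                    "classification": {"name": nuc.label.capitalize()},
                    "centroid_um": list(map(float, nuc.centroid)),
                    "measurements": {
                        "DAB: Mean": float(nuc.mean_dab),
                        "Area um^2": float(nuc.area_um2),
                        "Detection probability": float(nuc.detection_prob),
                    },
                },
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_detections(path: str | Path):
    """Reload a GeoJSON detections file written by :func:`write_detections`."""
    from .nuclei import Nucleus

    payload = json.loads(Path(path).read_text())
    out = []
    for feat in payload["features"]:
        props = feat["properties"]
        ring = feat["geometry"]["coordinates"][0]
        out.append(
            Nucleus(
                centroid=tuple(props["centroid_um"]),
                polygon=[tuple(v) for v in ring[:-1]],
                area_um2=props["measurements"]["Area um^2"],
                mean_dab=props["measurements"]["DAB: Mean"],
                label=props["classification"]["name"].lower(),
                detection_prob=props["measurements"]["Detection probability"],
            )
        )
    return out


def _fmt_li(summary: SlideSummary) -> str:
    if summary.n_pos + summary.n_neg == 0:
        return "NA"
    return f"{100.0 * summary.n_pos / (summary.n_pos + summary.n_neg):.2f}"


def write_slide_summary(summary: SlideSummary, path: str | Path) -> None:
    """Write the per-slide plain-text record (area in mm² to 4 decimals)."""
    lines = [
        f"slide_id: {summary.slide_id}",
        f"annotation_area_mm2: {summary.area_mm2:.4f}",
        f"total_detections: {summary.n_pos + summary.n_neg}",
        f"positive: {summary.n_pos}",
        f"negative: {summary.n_neg}",
        f"li_percent: {_fmt_li(summary)}",
        f"group: {summary.group}",
        f"descriptor: {summary.descriptor or ''}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_slide_summary(path: str | Path) -> SlideSummary:
    """Parse a record written by :func:`write_slide_summary`.

    The labeling index is recomputed from the counts so the round trip is
    exact rather than limited to the printed two decimals.
    """
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    return SlideSummary(
        slide_id=fields["slide_id"],
        group=fields.get("group", ""),
        descriptor=fields.get("descriptor") or None,
        n_pos=int(fields["positive"]),
        n_neg=int(fields["negative"]),
        area_mm2=float(fields["annotation_area_mm2"]),
    )


COHORT_COLUMNS = [
    "slide_id",
    "group",
    "descriptor",
    "n_pos",
    "n_neg",
    "area_mm2",
    "li_percent",
    "pos_density",
    "neg_density",
]


def append_cohort_row(summary: SlideSummary, path: str | Path) -> None:
    """Append one slide's summary as a CSV row, creating the header on first use."""
    path = Path(path)
    new = not path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(COHORT_COLUMNS)
        li = summary.li_percent
        writer.writerow(
            [
                summary.slide_id,
                summary.group,
                summary.descriptor or "",
                summary.n_pos,
                summary.n_neg,
                f"{summary.area_mm2:.6f}",
                "NA" if li is None or (isinstance(li, float) and math.isnan(li)) else f"{li:.6f}",
                f"{summary.pos_density:.6f}",
                f"{summary.neg_density:.6f}",
            ]
        )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV.

    Required columns: slide_id, path, group; optional: descriptor,
    has_control_tissue (truthy strings "1"/"true"/"yes").
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"slide_id", "path", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "descriptor" not in df.columns:
        df["descriptor"] = ""
    if "has_control_tissue" not in df.columns:
        df["has_control_tissue"] = "0"
    df["has_control_tissue"] = (
        df["has_control_tissue"].str.lower().isin({"1", "true", "yes"})
    )
    return df
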