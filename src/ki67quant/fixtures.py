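"""Synthetic brightfield H-DAB slide fixtures with exact ground truth.

The forward model is the same Beer–Lambert optics the pipeline inverts:
per-pixel optical density is a linear mix of a hematoxylin and a DAB
concentration plane, and RGB = (background+1)·10^(−OD·stain_vector) − 1.
Tissue is an elliptical region carrying a faint diffuse hematoxylin
counterstain plus a weak spatially smooth DAB background (nonspecific
chromogen), negative nuclei carry hematoxylin only, and positive nuclei
carry strong DAB with their hematoxylin largely masked by the chromogen —
as on real slides, where strongly positive nuclei read brown, not purple.
Artifact overlays (pen marks, dark debris, a left-side control-tissue
block, bright holes) exercise the artifact-removal stages.

Synthesis is a deterministic function of (FixtureSpec, seed), so every
pipeline stage can be tested against exact ground truth with no downloads.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon

from .stains import StainModel
from .wsi_io import SlideImage


# -- tiny distribution helpers (seedable, truncation by resampling) ---------

@dataclasses.dataclass
class Normal:
    mu: float
    sd: float
    low: float | None = None
    high: float | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = rng.normal(self.mu, self.sd, size=n)
        for _ in range(1000):
            bad = np.zeros(n, dtype=bool)
            if self.low is not None:
                bad |= out <= self.low if self.low > 0 else out < self.low
            if self.high is not None:
                bad |= out > self.high
            if not bad.any():
                return out
            out[bad] = rng.normal(self.mu, self.sd, size=int(bad.sum()))
        return np.clip(out, self.low, self.high)


@dataclasses.dataclass
class Uniform:
    low: float
    high: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=n)


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of one synthetic slide."""

    width_um: float = 1000.0
    height_um: float = 800.0
    mpp: float = 0.5
    n_positive: int = 25
    n_negative: int = 75
    placement: str | tuple = "uniform"      # or ("clustered", k, spread_um)
    dab_od_positive: Normal = dataclasses.field(
        default_factory=lambda: Normal(0.6, 0.1, low=0.3))
    # Immunonegative nuclei carry only faint nonspecific DAB, bounded well
    # below the positive range: a "negative" nucleus with strong DAB would
    # be a contradiction in terms, so the distribution has a hard ceiling.
    dab_od_negative: Normal = dataclasses.field(
        default_factory=lambda: Normal(0.03, 0.02, low=0.0, high=0.06))
    h_od: Normal = dataclasses.field(
        default_factory=lambda: Normal(0.5, 0.1, low=0.2))
    # DAB chromogen masks the blue counterstain in positive nuclei.
    h_suppression_positive: float = 0.05
    nucleus_radius_um: Uniform = dataclasses.field(
        default_factory=lambda: Uniform(3.0, 6.0))
    base_h_od: float = 0.15                 # diffuse counterstain in tissue
    base_dab_sigma: float = 0.04            # nonspecific DAB haze (OD)
    base_noise_scale_um: float = 50.0       # haze varies at tissue scale
    min_separation_um: float = 1.0          # gap between nucleus boundaries
    # Nuclei stay this far inside the tissue edge: the coarse pixel
    # classifier (4 μm grid, 32 μm Gaussian) cannot localize the boundary
    # more finely, and the phantom separates detection accuracy from
    # boundary-resolution effects.
    edge_margin_um: float = 40.0
    background_rgb: tuple[int, int, int] = (243, 243, 243)
    stain_model: StainModel | None = None
    artifacts: list = dataclasses.field(default_factory=list)
    # "center", or "right" to leave the left half free (a control block
    # always forces "right"); lets a control-block fixture be compared to a
    # geometrically identical fixture without the block.
    tissue_side: str = "center"
    pixel_noise_sd: float = 0.0             # gray levels, per channel
    seed: int = 0


@dataclasses.dataclass
class GroundTruth:
    """Exact per-nucleus and geometric truth for one synthetic slide."""

    centroids_um: np.ndarray            # (n, 2) x, y
    radii_um: np.ndarray
    classes: np.ndarray                 # array of "positive"/"negative"
    dab_od: np.ndarray                  # nominal per-nucleus DAB OD
    tissue_polygon: Polygon
    artifact_polygons: list[tuple[str, Polygon]]
    seed: int

    @property
    def n_positive(self) -> int:
        return int((self.classes == "positive").sum())

    @property
    def n_negative(self) -> int:
        return int((self.classes == "negative").sum())

    @property
    def li_percent(self) -> float:
        total = len(self.classes)
        return math.nan if total == 0 else 100.0 * self.n_positive / total


def spec_for_counts(
    n_positive: int, n_negative: int, seed: int,
    coverage: float = 0.3, **kwargs,
) -> FixtureSpec:
    """A :class:`FixtureSpec` sized so the requested counts pack feasibly.

    Random sequential placement with a minimum-separation rule jams near
    half coverage; the slide is sized so the nuclei's exclusion discs cover
    at most ``coverage`` of the usable tissue ellipse.
    """
    spec = FixtureSpec(n_positive=n_positive, n_negative=n_negative,
                       seed=seed, **kwargs)
    n = n_positive + n_negative
    r_mean = 0.5 * (spec.nucleus_radius_um.low + spec.nucleus_radius_um.high)
    excl = math.pi * (r_mean + 0.5 * spec.min_separation_um) ** 2
    semi = math.sqrt(n * excl / coverage / math.pi)   # usable ellipse radius
    side = (semi + spec.edge_margin_um + spec.nucleus_radius_um.high) / 0.4
    spec.width_um = max(spec.width_um, math.ceil(side))
    spec.height_um = max(spec.height_um, math.ceil(side))
    return spec


def _ellipse_polygon(cx, cy, a, b, n=128) -> Polygon:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon(np.stack([cx + a * np.cos(t), cy + b * np.sin(t)], axis=1))


def _tissue_geometry(spec: FixtureSpec):
    """Main tissue ellipse; shifted right when a control block is present."""
    w, h = spec.width_um, spec.height_um
    has_control = any(_artifact_type(a) == "control_block" for a in spec.artifacts)
    if has_control or spec.tissue_side == "right":
        return (0.74 * w, 0.5 * h, 0.20 * w, 0.40 * h)
    return (0.5 * w, 0.5 * h, 0.40 * w, 0.40 * h)


def _artifact_type(a) -> str:
    return a if isinstance(a, str) else a["type"]


def _artifact_params(a) -> dict:
    return {} if isinstance(a, str) else {k: v for k, v in a.items() if k != "type"}


def _place_nuclei(
    rng: np.random.Generator,
    spec: FixtureSpec,
    region: tuple[float, float, float, float],
    n: int,
    radii: np.ndarray,
    forbidden: list[Polygon],
) -> np.ndarray:
    """Rejection-sample nucleus centers inside an ellipse without overlap.

    Centers keep ``min_separation_um`` between nucleus boundaries (so the
    reference watershed is tested on proximity, not on pathological clumps)
    and stay clear of artifact polygons.
    """
    cx, cy, a, b = region
    accepted = np.empty((0, 2))
    acc_r: list[float] = []
    clustered = not isinstance(spec.placement, str)
    if clustered:
        _, k, spread = spec.placement
        centers_t = rng.uniform(0, 2 * math.pi, size=k)
        centers_r = np.sqrt(rng.uniform(0, 0.6, size=k))
        cluster_xy = np.stack(
            [cx + a * centers_r * np.cos(centers_t),
             cy + b * centers_r * np.sin(centers_t)], axis=1)

    max_attempts = 400 * n + 1000
    attempts = 0
    i = 0
    while i < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"infeasible packing: placed {i}/{n} nuclei in tissue region"
            )
        if clustered:
            c = cluster_xy[rng.integers(len(cluster_xy))]
            x, y = rng.normal(c, spec.placement[2], size=2)
        else:
            t = rng.uniform(0, 2 * math.pi)
            r = math.sqrt(rng.uniform(0, 1))
            x = cx + (a - radii[i] - spec.edge_margin_um) * r * math.cos(t)
            y = cy + (b - radii[i] - spec.edge_margin_um) * r * math.sin(t)
        # inside tissue ellipse with margin
        margin = radii[i] + spec.edge_margin_um
        if ((x - cx) / (a - margin)) ** 2 + ((y - cy) / (b - margin)) ** 2 > 1:
            continue
        if forbidden and any(p.contains(Point(x, y)) for p in forbidden):
            continue
        if len(accepted) and not clustered:
            d = np.hypot(accepted[:, 0] - x, accepted[:, 1] - y)
            min_d = radii[i] + np.array(acc_r) + spec.min_separation_um
            if (d < min_d).any():
                continue
        accepted = np.vstack([accepted, [x, y]])
        acc_r.append(radii[i])
        i += 1
    return accepted


def _smooth_noise(rng, shape, sigma_px, amplitude) -> np.ndarray:
    """Zero-mean spatially correlated noise field with the given sd."""
    if amplitude <= 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma_px, mode="reflect")
    sd = smooth.std()
    return smooth * (amplitude / sd) if sd > 0 else smooth


def _stamp_nucleus(h_plane, dab_plane, x_px, y_px, r_px, aspect, angle,
                   h_od, dab_od):
    """Composite one anti-aliased elliptical nucleus onto the OD planes.

    The nucleus replaces the underlying tissue OD weighted by its pixel
    coverage; anti-aliased edges make a nucleus's measured mean DAB sit
    slightly below its nominal OD, as on scanned slides.
    """
    a = r_px
    b = r_px * aspect
    pad = int(math.ceil(a)) + 2
    x0, x1 = int(x_px) - pad, int(x_px) + pad + 1
    y0, y1 = int(y_px) - pad, int(y_px) + pad + 1
    hgt, wid = h_plane.shape
    x0c, x1c = max(0, x0), min(wid, x1)
    y0c, y1c = max(0, y0), min(hgt, y1)
    if x0c >= x1c or y0c >= y1c:
        return
    ys, xs = np.mgrid[y0c:y1c, x0c:x1c]
    dx = (xs + 0.5) - x_px
    dy = (ys + 0.5) - y_px
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    d_norm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # signed distance (px) from the ellipse boundary, ≈ for mild eccentricity
    d_px = (d_norm - 1.0) * b
    cov = np.clip(0.5 - d_px, 0.0, 1.0)
    h_plane[y0c:y1c, x0c:x1c] = (1 - cov) * h_plane[y0c:y1c, x0c:x1c] + cov * h_od
    dab_plane[y0c:y1c, x0c:x1c] = (
        (1 - cov) * dab_plane[y0c:y1c, x0c:x1c] + cov * dab_od
    )


def generate_slide(spec: FixtureSpec) -> tuple[SlideImage, GroundTruth]:
    """Synthesize one slide and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    model = spec.stain_model or StainModel.default(background_rgb=spec.background_rgb)
    w_px = int(round(spec.width_um / spec.mpp))
    h_px = int(round(spec.height_um / spec.mpp))
    cx, cy, a, b = _tissue_geometry(spec)
    tissue_poly = _ellipse_polygon(cx, cy, a, b)

    # --- artifact geometry (built first so nuclei avoid it) ---------------
    artifact_polys: list[tuple[str, Polygon]] = []
    for art in spec.artifacts:
        kind = _artifact_type(art)
        params = _artifact_params(art)
        if kind == "pen_mark":
            start = params.get("start", (0.30 * spec.width_um, 0.12 * spec.height_um))
            end = params.get("end", (0.72 * spec.width_um, 0.30 * spec.height_um))
            width = params.get("width_um", 120.0)
            poly = LineString([start, end]).buffer(width / 2)
        elif kind == "dark_debris":
            center = params.get("center", (0.5 * spec.width_um, 0.85 * spec.height_um))
            radius = params.get("radius_um", 120.0)
            poly = Point(center).buffer(radius)
        elif kind == "control_block":
            poly = _ellipse_polygon(
                0.24 * spec.width_um, 0.5 * spec.height_um,
                0.17 * spec.width_um, 0.36 * spec.height_um,
            )
        elif kind == "bright_hole":
            center = params.get("center", (cx, cy))
            area = params.get("area_um2", 5000.0)
            poly = Point(center).buffer(math.sqrt(area / math.pi))
        else:
            raise ValueError(f"unknown artifact type {kind!r}")
        artifact_polys.append((kind, poly))

    forbidden = [p.buffer(spec.nucleus_radius_um.high) for _, p in artifact_polys]

    # --- nucleus catalog ---------------------------------------------------
    n_pos, n_neg = spec.n_positive, spec.n_negative
    n = n_pos + n_neg
    radii = spec.nucleus_radius_um.sample(rng, n)
    centers = (
        _place_nuclei(rng, spec, (cx, cy, a, b), n, radii, forbidden)
        if n else np.empty((0, 2))
    )
    classes = np.array(["positive"] * n_pos + ["negative"] * n_neg)
    rng.shuffle(classes)
    h_all = spec.h_od.sample(rng, n)
    dab_pos = spec.dab_od_positive.sample(rng, n)
    dab_neg = spec.dab_od_negative.sample(rng, n)
    is_pos = classes == "positive"
    dab_all = np.where(is_pos, dab_pos, dab_neg)
    h_all = np.where(is_pos, h_all * spec.h_suppression_positive, h_all)
    aspects = rng.uniform(0.75, 1.0, size=n)
    angles = rng.uniform(0, math.pi, size=n)

    # --- OD planes ---------------------------------------------------------
    ys, xs = np.mgrid[0:h_px, 0:w_px]
    x_um = (xs + 0.5) * spec.mpp
    y_um = (ys + 0.5) * spec.mpp
    in_tissue = ((x_um - cx) / a) ** 2 + ((y_um - cy) / b) ** 2 <= 1.0

    h_plane = np.where(in_tissue, spec.base_h_od, 0.0)
    noise_sigma_px = spec.base_noise_scale_um / spec.mpp
    dab_plane = np.where(
        in_tissue,
        np.abs(_smooth_noise(rng, (h_px, w_px), noise_sigma_px, spec.base_dab_sigma)),
        0.0,
    )

    for i in range(n):
        _stamp_nucleus(
            h_plane, dab_plane,
            centers[i, 0] / spec.mpp, centers[i, 1] / spec.mpp,
            radii[i] / spec.mpp, aspects[i], angles[i],
            h_all[i], dab_all[i],
        )

    # --- control-tissue block: second tissue + positive-heavy nuclei ------
    for kind, poly in artifact_polys:
        if kind != "control_block":
            continue
        bx, by = poly.centroid.x, poly.centroid.y
        minx, miny, maxx, maxy = poly.bounds
        ba, bb = (maxx - minx) / 2, (maxy - miny) / 2
        in_block = ((x_um - bx) / ba) ** 2 + ((y_um - by) / bb) ** 2 <= 1.0
        h_plane = np.where(in_block, spec.base_h_od, h_plane)
        n_ctrl = max(20, n // 4)
        ctrl_r = spec.nucleus_radius_um.sample(rng, n_ctrl)
        ctrl_xy = _place_nuclei(
            rng, spec, (bx, by, ba, bb), n_ctrl, ctrl_r, []
        )
        ctrl_dab = spec.dab_od_positive.sample(rng, n_ctrl)
        for j in range(n_ctrl):   # control tissue is predominantly positive
            _stamp_nucleus(
                h_plane, dab_plane,
                ctrl_xy[j, 0] / spec.mpp, ctrl_xy[j, 1] / spec.mpp,
                ctrl_r[j] / spec.mpp, 1.0, 0.0,
                spec.h_od.mu * spec.h_suppression_positive, ctrl_dab[j],
            )

    # bright holes reset the OD planes to glass
    for kind, poly in artifact_polys:
        if kind == "bright_hole":
            hx, hy = poly.centroid.x, poly.centroid.y
            hr = math.sqrt(poly.area / math.pi)
            in_hole = (x_um - hx) ** 2 + (y_um - hy) ** 2 <= hr**2
            h_plane = np.where(in_hole, 0.0, h_plane)
            dab_plane = np.where(in_hole, 0.0, dab_plane)

    # --- Beer–Lambert synthesis -------------------------------------------
    od = (
        h_plane[:, :, None] * model.h_vec[None, None, :]
        + dab_plane[:, :, None] * model.dab_vec[None, None, :]
    )
    bg = np.asarray(spec.background_rgb, dtype=float)
    rgb = (bg + 1.0) * np.power(10.0, -od) - 1.0

    # dark opaque artifacts override the transmitted light
    art_colors = {"pen_mark": (30, 40, 140), "dark_debris": (25, 18, 12)}
    for kind, poly in artifact_polys:
        if kind not in art_colors:
            continue
        minx, miny, maxx, maxy = poly.bounds
        sel = (
            (x_um >= minx) & (x_um <= maxx) & (y_um >= miny) & (y_um <= maxy)
        )
        idx = np.nonzero(sel)
        if len(idx[0]) == 0:
            continue
        from shapely import contains_xy

        inside = contains_xy(poly, x_um[idx], y_um[idx])
        rows, cols = idx[0][inside], idx[1][inside]
        rgb[rows, cols] = art_colors[kind]

    if spec.pixel_noise_sd > 0:
        rgb = rgb + rng.normal(0, spec.pixel_noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    slide = SlideImage(pixel_data=rgb, mpp=spec.mpp, slide_id=f"fixture_{spec.seed}")
    truth = GroundTruth(
        centroids_um=centers,
        radii_um=radii,
        classes=classes,
        dab_od=dab_all,
        tissue_polygon=tissue_poly,
        artifact_polygons=artifact_polys,
        seed=spec.seed,
    )
    return slide, truth


def write_fixture(slide: SlideImage, path: str | Path) -> None:
    """Write a fixture as flat TIFF with resolution tags plus an mpp sidecar."""
    import tifffile

    path = Path(path)
    ppcm = 1e4 / slide.mpp
    tifffile.imwrite(
        path, slide.pixel_data,
        resolution=(ppcm, ppcm), resolutionunit="CENTIMETER",
    )
    path.with_name(path.name + ".mpp.json").write_text(
        json.dumps({"mpp": slide.mpp})
    )


def generate_cohort(
    group_specs: Sequence[dict],
    seed: int,
    out_dir: str | Path,
    width_um: float = 700.0,
    height_um: float = 600.0,
) -> pd.DataFrame:
    """Generate a manifest of synthetic slides with group-level LI structure.

    Each entry of ``group_specs`` is a dict with keys ``name``, ``n_slides``,
    ``li`` (distribution of true LI percent) and ``density`` (distribution of
    total nuclei per mm² of tissue).  Slides, a manifest CSV and a
    ground-truth CSV are written to ``out_dir``; the manifest DataFrame is
    returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_rows = []
    truth_rows = []
    for gspec in group_specs:
        name = gspec["name"]
        for j in range(int(gspec["n_slides"])):
            slide_seed = int(rng.integers(0, 2**31 - 1))
            li = float(np.clip(gspec["li"].sample(rng, 1)[0], 0.0, 100.0))
            density = float(max(50.0, gspec["density"].sample(rng, 1)[0]))
            spec = FixtureSpec(
                width_um=width_um, height_um=height_um,
                n_positive=0, n_negative=0, seed=slide_seed,
            )
            ccx, ccy, ca, cb = _tissue_geometry(spec)
            area_mm2 = math.pi * ca * cb / 1e6
            n_total = max(10, int(round(density * area_mm2)))
            n_pos = int(round(li / 100.0 * n_total))
            spec.n_positive = n_pos
            spec.n_negative = n_total - n_pos
            slide, truth = generate_slide(spec)
            slide_id = f"{name}_{j:02d}"
            slide.slide_id = slide_id
            fname = f"{slide_id}.tif"
            write_fixture(slide, out_dir / fname)
            manifest_rows.append(
                {
                    "slide_id": slide_id,
                    "path": fname,
                    "group": name,
                    "descriptor": "",
                    "has_control_tissue": 0,
                }
            )
            truth_rows.append(
                {
                    "slide_id": slide_id,
                    "group": name,
                    "true_n_pos": truth.n_positive,
                    "true_n_neg": truth.n_negative,
                    "true_li_percent": truth.li_percent,
                    "seed": slide_seed,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
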