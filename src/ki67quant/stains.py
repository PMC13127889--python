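"""Stain physics: optical density, per-slide stain vectors, deconvolution.

Brightfield H-DAB slides mix two dyes — hematoxylin (blue, all nuclei) and
diaminobenzidine (DAB, brown, Ki-67-positive nuclei).  In optical density
(OD = −log10 of transmittance) the dyes add linearly (Beer–Lambert), so an
RGB pixel can be unmixed into per-stain concentrations given each dye's unit
OD color vector.  Published generic H-DAB vectors are good defaults, but the
actual colors drift with staining protocol and scanner, so the vectors and
the background white point are re-estimated per slide from the tissue
pixels before deconvolution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

# Generic H-DAB stain matrix (unit OD vectors, RGB order).
DEFAULT_H_VEC = np.array([0.651, 0.701, 0.290])
DEFAULT_H_VEC /= np.linalg.norm(DEFAULT_H_VEC)
DEFAULT_DAB_VEC = np.array([0.269, 0.568, 0.778])
DEFAULT_DAB_VEC /= np.linalg.norm(DEFAULT_DAB_VEC)

#: A red-heavy hematoxylin vector signals weak blue staining: the dye signal
#: is so faint that the estimated vector drifts toward the residual/red axis.
WEAK_H_COMPONENT = 0
WEAK_H_CUTOFF = 0.7


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero stain vector")
    return v / n


@dataclasses.dataclass
class StainModel:
    """Per-slide stain basis: H, DAB and residual unit OD vectors + background.

    ``weak_hematoxylin`` is a deterministic function of the hematoxylin
    vector: true iff its red component is at least ``weak_h_cutoff``.
    Downstream it raises the tissue threshold and switches nucleus
    normalization from per-tile to whole-image.
    """

    h_vec: np.ndarray
    dab_vec: np.ndarray
    res_vec: np.ndarray = None  # type: ignore[assignment]
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    weak_h_component: int = WEAK_H_COMPONENT
    weak_h_cutoff: float = WEAK_H_CUTOFF

    def __post_init__(self) -> None:
        self.h_vec = _unit(np.asarray(self.h_vec, dtype=float))
        self.dab_vec = _unit(np.asarray(self.dab_vec, dtype=float))
        if self.res_vec is None:
            self.res_vec = _unit(np.cross(self.h_vec, self.dab_vec))
        else:
            self.res_vec = _unit(np.asarray(self.res_vec, dtype=float))
        self.background_rgb = tuple(int(c) for c in self.background_rgb)

    @property
    def weak_hematoxylin(self) -> bool:
        return bool(self.h_vec[self.weak_h_component] >= self.weak_h_cutoff)

    @property
    def matrix(self) -> np.ndarray:
        """Stain basis as rows (h, dab, res): shape (3, 3)."""
        return np.stack([self.h_vec, self.dab_vec, self.res_vec])

    @classmethod
    def default(cls, background_rgb=(255, 255, 255)) -> "StainModel":
        return cls(
            h_vec=DEFAULT_H_VEC.copy(),
            dab_vec=DEFAULT_DAB_VEC.copy(),
            background_rgb=background_rgb,
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "h_vec": self.h_vec.tolist(),
            "dab_vec": self.dab_vec.tolist(),
            "res_vec": self.res_vec.tolist(),
            "background_rgb": list(self.background_rgb),
            "weak_h_component": self.weak_h_component,
            "weak_h_cutoff": self.weak_h_cutoff,
            "weak_hematoxylin": self.weak_hematoxylin,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StainModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            h_vec=np.array(d["h_vec"]),
            dab_vec=np.array(d["dab_vec"]),
            res_vec=np.array(d["res_vec"]),
            background_rgb=tuple(d["background_rgb"]),
            weak_h_component=d.get("weak_h_component", WEAK_H_COMPONENT),
            weak_h_cutoff=d.get("weak_h_cutoff", WEAK_H_CUTOFF),
        )


def rgb_to_od(pixels: np.ndarray, background_rgb) -> np.ndarray:
    """Beer–Lambert transform of an RGB raster against a background white point.

    ``OD_c = −log10((I_c + 1) / (bg_c + 1))``, clipped below at zero.  The +1
    offset avoids log(0) at fully absorbing pixels; pixels brighter than the
    background carry no stain information and clip to OD 0.
    """
    bg = np.asarray(background_rgb, dtype=float)
    if np.any(bg < 1):
        raise ValueError("background components must be >= 1")
    od = -np.log10((pixels.astype(float) + 1.0) / (bg + 1.0))
    return np.clip(od, 0.0, None)


def estimate_background(region: np.ndarray, sigma: float = 2.0,
                        luminance_pct: float = 75.0) -> tuple[int, int, int]:
    """Most frequent RGB value of the bright (glass) part of the slide.

    Each channel is Gaussian-smoothed (``sigma`` px) to suppress scanner
    noise, then the per-channel mode is taken over pixels whose luminance
    exceeds the ``luminance_pct`` percentile; if that cut leaves nothing
    (constant image), the global per-channel mode is used.
    """
    if region.size == 0:
        raise ValueError("empty region")
    smoothed = np.empty_like(region, dtype=float)
    for c in range(3):
        smoothed[:, :, c] = ndimage.gaussian_filter(
            region[:, :, c].astype(float), sigma=sigma, mode="reflect"
        )
    lum = smoothed.mean(axis=2)
    cut = np.percentile(lum, luminance_pct)
    bright = lum > cut
    if not bright.any():
        bright = np.ones_like(lum, dtype=bool)
    vals = np.clip(np.rint(smoothed[bright]), 0, 255).astype(int)
    mode = tuple(int(np.bincount(vals[:, c], minlength=256).argmax()) for c in range(3))
    return mode


def _geometric_median(points: np.ndarray, n_iter: int = 100, tol: float = 1e-9) -> np.ndarray:
    """Weiszfeld iteration; robust central direction of an OD point cloud."""
    y = points.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(points - y, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        w = 1.0 / d
        y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def estimate_stain_vectors(
    region: np.ndarray,
    tissue_mask: np.ndarray,
    defaults: StainModel | None = None,
    od_gate: tuple[float, float] = (0.05, 1.0),
    min_mask_pixels: int = 100,
    min_cluster_pixels: int = 50,
    smooth_sigma: float = 2.0,
) -> StainModel:
    """Estimate per-slide H and DAB vectors from tissue pixels.

    The masked pixels are OD-transformed against the estimated background and
    gated to total OD in ``od_gate`` (dropping glass and saturated pigment).
    Each OD vector is assigned to the H or DAB cluster by the angle of its
    projection in the plane spanned by the default H and DAB directions; each
    cluster is then refined to its extreme-angle decile — the bluest blues
    and the brownest browns — because pixels near the split are stain
    mixtures (positive-nucleus edges, DAB haze over counterstain) whose
    inclusion would drag both vectors toward each other.  The new vector is
    the normalized geometric median of the refined subset, falling back to
    the default vector for clusters below ``min_cluster_pixels``.
    """
    defaults = defaults or StainModel.default()
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    background = estimate_background(region, sigma=smooth_sigma)

    if tissue_mask.sum() < min_mask_pixels:
        return StainModel(
            h_vec=defaults.h_vec,
            dab_vec=defaults.dab_vec,
            background_rgb=background,
            weak_h_component=defaults.weak_h_component,
            weak_h_cutoff=defaults.weak_h_cutoff,
        )

    smoothed = np.empty_like(region, dtype=float)
    for c in range(3):
        smoothed[:, :, c] = ndimage.gaussian_filter(
            region[:, :, c].astype(float), sigma=smooth_sigma, mode="reflect"
        )
    od = rgb_to_od(smoothed, background)[tissue_mask]
    total = od.sum(axis=1)
    od = od[(total >= od_gate[0]) & (total <= od_gate[1])]

    h_vec, dab_vec = defaults.h_vec.copy(), defaults.dab_vec.copy()
    if len(od):
        # Angle in the (default-H, default-DAB) plane decides cluster
        # membership: the midpoint angle separates blue-ish from brown-ish.
        e1 = defaults.h_vec
        e2 = _unit(defaults.dab_vec - (defaults.dab_vec @ e1) * e1)
        ang_h = 0.0
        ang_dab = np.arctan2(defaults.dab_vec @ e2, defaults.dab_vec @ e1)
        split = 0.5 * (ang_h + ang_dab)
        ang = np.arctan2(od @ e2, od @ e1)
        h_cluster = od[ang <= split]
        dab_cluster = od[ang > split]
        if len(h_cluster) >= min_cluster_pixels:
            h_ang = ang[ang <= split]
            pure = h_cluster[h_ang <= np.percentile(h_ang, 10)]
            h_vec = _unit(_geometric_median(pure))
        if len(dab_cluster) >= min_cluster_pixels:
            d_ang = ang[ang > split]
            pure = dab_cluster[d_ang >= np.percentile(d_ang, 90)]
            dab_vec = _unit(_geometric_median(pure))

    return StainModel(
        h_vec=h_vec,
        dab_vec=dab_vec,
        background_rgb=background,
        weak_h_component=defaults.weak_h_component,
        weak_h_cutoff=defaults.weak_h_cutoff,
    )


def deconvolve(pixels: np.ndarray, model: StainModel) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB raster into hematoxylin and DAB OD coefficient rasters.

    The OD vector of every pixel is expressed in the (h, dab, residual)
    basis by the exact linear inverse; negative coefficients (noise outside
    the dye gamut) are clipped to zero.
    """
    basis = model.matrix  # rows: h, dab, res
    if abs(np.linalg.det(basis)) < 1e-6:
        raise ValueError("stain basis is singular (vectors nearly collinear)")
    od = rgb_to_od(pixels, model.background_rgb)
    coeffs = od.reshape(-1, 3) @ np.linalg.inv(basis)
    coeffs = coeffs.reshape(od.shape)
    h = np.clip(coeffs[..., 0], 0.0, None)
    dab = np.clip(coeffs[..., 1], 0.0, None)
    return h, dab


def angular_distance_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two stain vectors in degrees (orientation-insensitive)."""
    cosang = abs(float(_unit(np.asarray(u, float)) @ _unit(np.asarray(v, float))))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
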