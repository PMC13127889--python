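"""Flat, namespaced pipeline configuration with provenance.

Every tunable of the pipeline lives here under a ``stage.key`` name so a run
can write the fully resolved configuration beside its outputs and be
reproduced exactly.  Values can be overridden from a JSON or TOML file or a
plain mapping; unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

from . import __version__

#: Default value for every configuration key.
DEFAULTS: dict[str, Any] = {
    # wsi_io
    "io.mpp_override": None,            # μm/px for files without metadata
    "io.control_crop_fraction": 0.5,    # left fraction removed on control slides
    # stain_model
    "stain.od_gate_low": 0.05,          # total-OD gate for vector estimation
    "stain.od_gate_high": 1.0,
    "stain.min_mask_pixels": 100,
    "stain.min_cluster_pixels": 50,
    "stain.background_smooth_sigma": 2.0,
    "stain.estimation_mpp": 0.5,        # fine enough for pure nucleus interiors
    "stain.background_luminance_pct": 75.0,
    "stain.weak_h_component": 0,        # index into (R, G, B) of the H vector
    "stain.weak_h_cutoff": 0.7,
    # tissue_segmentation
    "tissue.working_mpp": 4.0016,       # μm/px of the pixel-classifier grid
    "tissue.gaussian_sigma_px": 8.0,
    "tissue.preliminary_threshold": 80.0,
    "tissue.preliminary_min_area_um2": 20_000.0,
    "tissue.refined_min_area_um2": 10_000.0,
    "tissue.min_hole_area_um2": 8_000.0,
    "tissue.margin_strong": 40.0,       # background_red − margin = custom threshold
    "tissue.margin_weak": 15.0,
    "tissue.threshold_clamp": (10.0, 250.0),
    # nucleus_segmentation
    "nuclei.backend": "reference",
    "nuclei.prob_threshold": 0.25,
    "nuclei.target_mpp": 0.5,
    "nuclei.tile_px": 1024,
    "nuclei.overlap_px": 64,
    "nuclei.norm_p_low": 1.0,
    "nuclei.norm_p_high": 99.0,
    "nuclei.min_area_um2": 10.0,
    "nuclei.max_area_um2": 400.0,
    "nuclei.max_od": 1.2,               # saturated-pigment gate (combined OD)
    # classification
    "classify.downsample": 4,
    "classify.hist_bins": 256,
    "classify.hist_od_max": 2.0,
    # density_maps
    "density.grid_mpp": 8.0,
    "density.radius_um": 50.0,
    "density.kernel": "disk",           # "disk" honors the search-radius rule
    "density.colormap": "jet",
    # cohort_stats
    "stats.alpha": 0.05,
    "stats.icc_form": "ICC2",           # two-way random, absolute agreement, single
}


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration: :data:`DEFAULTS` plus user overrides."""

    values: dict[str, Any] = dataclasses.field(default_factory=lambda: dict(DEFAULTS))

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def override(self, overrides: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(overrides) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(self.values)
        merged.update(overrides)
        return PipelineConfig(merged)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls().override(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self) -> dict[str, Any]:
        return {"package_version": __version__, "config_hash": self.config_hash()}

    def dump(self, path: str | Path | None = None) -> str:
        payload = dict(self.values)
        payload["_provenance"] = self.provenance()
        text = json.dumps(payload, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text
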