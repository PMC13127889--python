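"""Estimate per-slide stain vectors and check them against the synthesis truth.

The fixture is composited with the published generic H-DAB optical-density
vectors; estimation should recover both within ~2 degrees, and a slide
synthesized with a red-shifted hematoxylin vector should trip the
weak-hematoxylin flag (red component >= 0.7).
"""

import numpy as np

from ki67quant import (
    DEFAULT_DAB_VEC,
    DEFAULT_H_VEC,
    StainModel,
    generate_slide,
    segment_preliminary,
)
from ki67quant.fixtures import spec_for_counts
from ki67quant.pipeline import _mask_on_raster
from ki67quant.stains import angular_distance_deg, estimate_stain_vectors

slide, truth = generate_slide(spec_for_counts(150, 350, seed=5))
mask = _mask_on_raster(segment_preliminary(slide), slide)
model = estimate_stain_vectors(slide.pixel_data, mask)

print("estimated H vector:  ", np.round(model.h_vec, 3))
print("estimated DAB vector:", np.round(model.dab_vec, 3))
print(f"H error:   {angular_distance_deg(model.h_vec, DEFAULT_H_VEC):.2f} deg")
print(f"DAB error: {angular_distance_deg(model.dab_vec, DEFAULT_DAB_VEC):.2f} deg")
print("weak hematoxylin flag:", model.weak_hematoxylin)

# a red-heavy hematoxylin vector signals weak staining
rest = np.array([0.0, DEFAULT_H_VEC[1], DEFAULT_H_VEC[2]])
rest /= np.linalg.norm(rest)
weak = StainModel(h_vec=0.75 * np.array([1.0, 0, 0]) + np.sqrt(1 - 0.75**2) * rest,
                  dab_vec=DEFAULT_DAB_VEC)
print("red component 0.75 ->", weak.weak_hematoxylin,
      "(raises the tissue threshold, switches to image-level normalization)")
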