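"""Minimum-error threshold selection on a CT-like intensity histogram.

Builds a two-class histogram (soft tissue vs bone), selects the bone
threshold by the minimum-error criterion, and a separate high-intensity
threshold isolating metal (prosthesis) voxels.
"""

import numpy as np
from scipy.stats import norm

from femurssm.segmentation import (
    IntensityHistogram,
    high_intensity_threshold,
    kittler_illingworth_threshold,
)

# soft tissue ~ N(100, 20^2) HU-like units, bone ~ N(300, 30^2),
# plus a small saturated metal peak near 500
edges = np.linspace(0, 512, 513)
centers = 0.5 * (edges[:-1] + edges[1:])
counts = (
    0.70 * norm.pdf(centers, 100, 20)
    + 0.29 * norm.pdf(centers, 300, 30)
    + 0.01 * norm.pdf(centers, 500, 5)
) * 1e6
hist = IntensityHistogram(edges, counts)

bone_t = kittler_illingworth_threshold(hist)
metal_t = high_intensity_threshold(hist, quantile=0.995)

print(f"bone threshold (minimum-error criterion): {bone_t:.0f}")
print(f"metal band lower edge (99.5% quantile):   {metal_t:.0f}")

# Everything above bone_t segments as bone; the narrow band above
# metal_t isolates the prosthesis so it can be masked out before the
# damaged bone is reconstructed.
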