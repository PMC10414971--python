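"""Build equivolumetric surfaces on a folded-cortex model and profile qT1.

A wedge cortex (outer area twice the inner area, like a gyral crown)
makes the difference between equidistant and equivolumetric placement
visible: the equivolumetric surfaces crowd toward the larger outer
surface so that each of the 13 gaps holds the same tissue volume. A qT1
field increasing linearly with depth (myelin decreasing toward the pial
surface) is sampled on the 12 surfaces and averaged into parcels and
depth compartments.
"""

import numpy as np

from gradplast import build_laminar_stack, compartment_means, parcel_profiles, sample_field
from gradplast.synthetic import (
    make_cortex, make_grid_parcellation, make_qt1_field, sheet_depth_geometry,
)

thickness = 3.0
cortex = make_cortex("wedge", n_vertices=900, thickness=thickness, area_ratio=2.0)
stack = build_laminar_stack(cortex, n_surfaces=12)

print("distance fraction (from white) of each surface at one vertex:")
print(np.round(stack.rho[:, 0], 3), "(equidistant would be 12/13 ... 1/13)")

field, _ = make_qt1_field(lambda depth, region: 1400.0 + 500.0 * depth,
                          sheet_depth_geometry(thickness))
samples = sample_field(stack, field)
parcels = make_grid_parcellation(cortex.n_vertices, 4)
profiles = parcel_profiles(samples, parcels)
comps = compartment_means(profiles)

print("parcel 0 depth profile (ms):", np.round(profiles.values[0], 1))
print("compartment means (ms): superficial %.1f, middle %.1f, deep %.1f"
      % (comps["superficial"][0], comps["middle"][0], comps["deep"][0]))
# Superficial compartments sit near the pial surface (low depth fraction,
# here low qT1 input near 1400 ms); deep compartments approach the
# white-matter boundary (near 1900 ms).
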