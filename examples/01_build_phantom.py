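"""Build an infant-sized five-layer head phantom and place the 10-10 system.

The phantom is a concentric sphere (scalp/skull/CSF/GM/WM) with age-specific
scalp and skull thicknesses and a synthetic cortical parcellation.  Landmarks
and the 61 fiducial points of the 10-10 system are placed on its surface.
"""

import numpy as np

from nirscc import (
    PhantomSpec,
    build_sphere_phantom,
    place_fiducials_1010,
    place_landmarks,
)

spec = PhantomSpec.for_age("0yo", voxel_size=1.0)
model = build_sphere_phantom(spec)
lm = place_landmarks(model)
fids = place_fiducials_1010(model, lm)

counts = {name: int((model.labels == i).sum()) for i, name in
          enumerate(["air", "scalp", "skull", "csf", "gm", "wm"])}
print(f"phantom grid {model.shape}, voxel {model.voxel_size} mm")
print("voxels per tissue:", counts)
print(f"brain parcels: {model.n_regions()}")
print(f"fiducials placed: {len(fids)}; Cz at {np.round(fids['Cz'], 1)} mm")
print(f"T3/T4 mirror error: {np.abs(fids['T3'] - fids['T4']*[-1,1,1]).max():.2e} mm")
# The tissue counts reflect the nested shells (scalp 3.5 mm, skull 2.2 mm for
# a 0-year-old); the mirror error shows the left/right symmetry of the 10-10
# construction on a symmetric head.
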