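"""Correct a tinted scan and summarize georeferencing error.

White balance: each band is scaled by luminance/reference so the sheet's
white paper margin becomes neutral gray. Dislocation error: the RMSE of
2-D control-point residuals against modern reference geometry.
"""

import numpy as np

from mapchange.preprocess import (ControlPointSet, estimate_white_reference,
                                  georeference_rmse, white_balance)
from mapchange.synthmap import RenderStyle, generate_scene, render_sheet
from mapchange.pipeline import find_white_patch

# a yellowed sheet, as an aged 1965 print would scan
scene = generate_scene((1.0, 1.0), seed=7)
rgb, _ = render_sheet(scene, RenderStyle(color_cast=(1.03, 1.0, 0.88)))

patch = find_white_patch(rgb)
ref = estimate_white_reference(rgb, patch)
balanced = white_balance(rgb, ref)
print(f"white patch at {patch}, reference "
      f"({ref.r_ref:.0f}, {ref.g_ref:.0f}, {ref.b_ref:.0f})")

def patch_means(raster):
    return raster.window(*patch).data.reshape(-1, 3).mean(axis=0).round(1)

print("white patch means before:", patch_means(rgb))
print("white patch means after: ", patch_means(balanced))
# after balancing the patch is neutral gray: the paper tint is gone

# dislocation error of synthetic control points with ~7 m scatter
rng = np.random.default_rng(0)
residuals = rng.normal(0.0, 5.0, size=(20, 2))
points = ControlPointSet(residuals)
print(f"dislocation RMSE over {points.n} control points: "
      f"{georeference_rmse(points):.2f} m")
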