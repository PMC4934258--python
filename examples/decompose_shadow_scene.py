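"""Decompose a textured scene under a sharp-edged shadow.

Builds a 128x128 synthetic image (known reflectance x illumination), runs
the variable-exponent decomposition with the synthetic-protocol settings
(lambda=80, gamma=1e3, w=1e9), and reports how well the recovered
illumination matches the ground truth.
"""

import numpy as np

from pxretinex import SolverParams, enhance_gray, make_shadow_scene

scene = make_shadow_scene(128, 128, "filtered_noise", interior_level=0.3,
                          edge_sharpness=4.0, seed=1)
result = enhance_gray(scene.composite, SolverParams(w=1e9), gamma=None)

log_err = result.log_illumination - np.log(scene.illumination_true)
rmse = np.sqrt(np.mean((log_err - log_err.mean()) ** 2))

inner = scene.region_masks["shadow_interior"]
outer = scene.region_masks["shadow_exterior"]
R = result.reflectance
print(f"outer iterations:            {result.trace.iterations_run} "
      f"(converged={result.trace.converged})")
print(f"log-illumination RMSE:       {rmse:.4f}   (offset-free; 0 = perfect)")
print(f"input shadow ratio:          {scene.composite[inner].mean() / scene.composite[outer].mean():.3f}")
print(f"reflectance shadow ratio:    {R[inner].mean() / R[outer].mean():.3f}   (1 = shadow fully removed)")

# The input is ~3x darker inside the shadow; after decomposition the
# reflectance is nearly flat across the shadow edge - the shadow has been
# absorbed into the illumination component.
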