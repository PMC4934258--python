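"""Full enhancement chain plus the evaluation triplet.

Builds an unevenly lit scene, enhances it (decomposition + gamma-corrected
recombination), and scores the recovered reflectance against the known
ground truth with SNR / SSIM / CIEDE2000.
"""

import numpy as np

from pxretinex import (GammaConfig, SolverParams, compose, enhance_gray,
                       evaluate, make_illumination, make_texture)

texture = make_texture(128, 128, "filtered_noise", seed=4)
light = make_illumination(128, 128, "gaussian_spot", seed=4, low=0.25)
scene = compose(texture, light)

result = enhance_gray(scene.composite, SolverParams(w=1e9),
                      gamma=GammaConfig(s=2.2, white_value=255.0))

# score recovered reflectance against the true texture (mean-matched scale,
# since the decomposition fixes the reflectance level only up to a constant)
r_true = 255.0 * scene.reflectance_true
r_rec = 255.0 * result.reflectance
r_rec *= r_true.mean() / r_rec.mean()
report = evaluate(r_true, r_rec)

print(f"iterations: {result.trace.iterations_run}  converged: {result.trace.converged}")
print(f"SNR:       {report.snr_db:6.2f} dB   (higher = closer to the true texture)")
print(f"SSIM:      {report.ssim:6.4f}      (1 = identical structure)")
print(f"CIEDE2000: {report.ciede2000_mean:6.3f}     (0 = no perceptual difference)")
print(f"output range after gamma-corrected recombination: "
      f"[{result.output.min():.1f}, {result.output.max():.1f}]")
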