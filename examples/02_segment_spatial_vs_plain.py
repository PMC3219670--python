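"""Segment a noisy phantom with plain GMM-EM and with the spatial variant.

The spatial fit blends each pixel's density with the density of its
neighbourhood average, weighted by beta estimated from the background
noise.  At 9% Rician noise this visibly raises the Dice similarity index.
"""

import numpy as np

from emseg import SpatialConfig, evaluate, fit_em1, fit_gmm, generate_phantom

phantom = generate_phantom((64, 64), n_classes=4, seed=3)
noisy = phantom.noisy(9.0, seed=3)

plain = fit_gmm(noisy, M=4, seed=3)
spatial = fit_em1(noisy, M=4, config=SpatialConfig(window=3), seed=3,
                  background_mask=phantom.truth == 0)

rho_plain = evaluate(plain.labels, phantom.truth, image=noisy).averages["rho"]
rho_spatial = evaluate(spatial.labels, phantom.truth, image=noisy).averages["rho"]

print(f"resolved beta          : {spatial.beta:.4f}")
print(f"Dice, plain GMM-EM     : {rho_plain:.4f}")
print(f"Dice, spatial (EM-1)   : {rho_spatial:.4f}")
print(f"fitted means (spatial) : {np.sort(spatial.params.means.ravel()).round(3).tolist()}")
# beta tracks the noise level (~0.07 at 9% noise on unit-normalized
# intensities), so the smoothing switches itself off on clean images.
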