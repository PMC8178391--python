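"""Total-variation baseline on a noisy piecewise-constant phantom.

Reconstructs min_x 0.5*||Ax - y||^2 + lambda*TV(x) with Chambolle-Pock for a
small grid of regularization weights and reports the MSE against the ground
truth, next to plain FBP.
"""

import numpy as np

from n2itomo import (
    ImageSlice,
    NoiseConfig,
    TvConfig,
    fbp_reconstruct,
    forward_project,
    make_geometry,
    simulate_noisy_sinogram,
    tvmin_reconstruct,
)

N = 96
c = (N - 1) / 2
ii, jj = np.ogrid[:N, :N]
img = ((ii - c) ** 2 + (jj - c) ** 2 <= 30**2) * 0.01
img = img + (((ii - c - 12) ** 2 + (jj - c + 8) ** 2) <= 8**2) * 0.01
geom = make_geometry(144, np.pi, 0.0, N, N)
noisy = simulate_noisy_sinogram(
    forward_project(ImageSlice(img), geom),
    NoiseConfig(incident_photon_count=500, seed=0),
)

mse_fbp = float(np.mean((fbp_reconstruct(noisy).values - img) ** 2))
print(f"noisy FBP MSE: {mse_fbp:.3e}")
for lam in np.logspace(0, 2, 5):
    out = tvmin_reconstruct(noisy, TvConfig(lam=lam, iterations=500)).values
    print(f"TV-MIN lambda={lam:7.2f}: MSE {float(np.mean((out - img) ** 2)):.3e}")
print(
    "A well-chosen lambda beats FBP clearly on this piecewise-constant "
    "object; too small leaves noise, too large flattens real structure "
    "(stair-casing is TV's characteristic failure on fine detail)."
)
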