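"""Multi-channel (diffraction-tomography-like) denoising.

Each scattering channel yields its own sinogram of the same slice; the
per-voxel vector over channels (the diffractogram) identifies the local
material, so identical materials share identical channel vectors.  Training
splits each channel's sinogram identically in angle and keeps the full
channel stack in both input and target, letting the network exploit the
cross-channel structure.
"""

import numpy as np

from n2itomo import (
    ImageSlice,
    ModelConfig,
    NoiseConfig,
    TrainingConfig,
    build_msd,
    denoise_full,
    forward_project,
    make_geometry,
    make_training_pairs,
    multichannel_split,
    simulate_noisy_sinogram,
    spectral_phantom,
    train,
)
from n2itomo.training import reconstruct_stack

N, C, num_angles, J = 64, 11, 180, 3

slice_ = spectral_phantom(N, num_materials=4, C=C, seed=0)
truth = slice_.channel_volume()
geom = make_geometry(num_angles, np.pi, 0.0, N, N)
noisy = []
for c in range(C):
    clean = forward_project(ImageSlice(truth[c]), geom)
    clean.channel_index = c
    noisy.append(
        simulate_noisy_sinogram(
            clean, NoiseConfig(incident_photon_count=500, seed=100 + c)
        )
    )

scheme = multichannel_split(noisy, J)
pairs = make_training_pairs(noisy, scheme, "multichannel")
model = build_msd(
    ModelConfig(depth=12, in_channels=C, out_channels=C, weight_init_seed=1)
)
model, _ = train(
    pairs, model, TrainingConfig(iterations=400, batch_size=1, shuffle_seed=2)
)

noisy_fbp = reconstruct_stack(noisy)
denoised = denoise_full(model, noisy, "full", scheme)
improved = sum(
    np.mean((denoised[c] - truth[c]) ** 2) < np.mean((noisy_fbp[c] - truth[c]) ** 2)
    for c in range(C)
)
print(f"channels with lower MSE after denoising: {improved} / {C}")
for c in range(0, C, 3):
    a = float(np.mean((noisy_fbp[c] - truth[c]) ** 2))
    b = float(np.mean((denoised[c] - truth[c]) ** 2))
    print(f"  channel {c:2d}: noisy FBP MSE {a:.2e} -> denoised {b:.2e}")
print(
    "Every channel is reconstructed and denoised jointly; improvement across "
    "(nearly) all channels shows the network used the shared diffractogram "
    "structure rather than fitting single-channel noise."
)
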